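"""CSV / YAML formats, configuration and provenance stamping.

Column names embed units (``time_s``, ``conc_uM``, ``rate_per_s``) to
prevent silent unit drift.  Every CLI run emits a :class:`RunManifest`
recording the command, config hash, seeds and package version, so that a
run can be reproduced bit-identically from its manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from .curves import ProgressCurve
from .schemes import RateScheme, build_scheme, scheme_to_spec

__all__ = [
    "SCHEMA_VERSION",
    "RunManifest",
    "read_progress_csv",
    "write_progress_csv",
    "load_scheme_yaml",
    "save_scheme_yaml",
    "load_config",
    "write_manifest",
]

SCHEMA_VERSION = 1

_REQUIRED = ("replicate", "time_s", "fraction_pause_rna")


def read_progress_csv(path) -> list[ProgressCurve]:
    """Read replicated progress curves from CSV.

    Required columns: ``replicate``, ``time_s``, ``fraction_pause_rna``;
    optional ``sd`` and ``species``.  Errors name the offending column or
    row.
    """
    df = pd.read_csv(path)
    for col in _REQUIRED:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    for col in ("time_s", "fraction_pause_rna") + (("sd",) if "sd" in df else ()):
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any():
            row = int(numeric.isna().idxmax())
            raise ValueError(
                f"{path}: non-numeric value {df[col][row]!r} in column "
                f"{col!r} at row {row}"
            )
        df[col] = numeric

    curves = []
    group_cols = ["replicate"] + (["species"] if "species" in df else [])
    for key, grp in df.groupby(group_cols, sort=True):
        rep = key[0] if isinstance(key, tuple) else key
        species = key[1] if isinstance(key, tuple) and len(key) > 1 else "pause_rna"
        t = grp["time_s"].to_numpy()
        if t.size > 1 and not (pd.Series(t).diff().dropna() > 0).all():
            raise ValueError(
                f"{path}: time_s not strictly increasing within replicate {rep}"
            )
        y = grp["fraction_pause_rna"].to_numpy()
        bad = (y < -0.25) | (y > 1.25)
        if bad.any():
            row = grp.index[bad.argmax()]
            raise ValueError(
                f"{path}: fraction {y[bad.argmax()]:g} outside [0, 1] at row {row}"
            )
        curves.append(
            ProgressCurve(
                t, y,
                sd=grp["sd"].to_numpy() if "sd" in grp else None,
                replicate=int(rep), species=str(species),
            )
        )
    if not curves:
        raise ValueError(f"{path}: no data rows")
    return curves


def write_progress_csv(curves: list[ProgressCurve], path) -> None:
    rows = []
    for c in curves:
        df = pd.DataFrame(
            {"replicate": c.replicate, "species": c.species,
             "time_s": c.times, "fraction_pause_rna": c.fractions}
        )
        if c.sd is not None:
            df["sd"] = c.sd
        rows.append(df)
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def load_scheme_yaml(path) -> RateScheme:
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    version = spec.pop("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ValueError(f"{path}: unsupported schema_version {version}")
    return build_scheme(spec)


def save_scheme_yaml(scheme: RateScheme, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scheme_to_spec(scheme), fh, sort_keys=False)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


@dataclass
class RunManifest:
    """Provenance record of one CLI run."""

    command: str
    seed: int | None
    config_hash: str
    package_version: str
    timestamp_utc: str
    inputs: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    frozen_parameters: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _hash_config(obj) -> str:
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(
    out_dir,
    command: str,
    seed: int | None,
    config: dict | None = None,
    inputs: list[str] | None = None,
    outputs: list[str] | None = None,
    frozen_parameters: dict | None = None,
) -> Path:
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        command=command,
        seed=seed,
        config_hash=_hash_config(config or {}),
        package_version=__version__,
        timestamp_utc=datetime.now(timezone.utc).isoformat(),
        inputs=[str(p) for p in (inputs or [])],
        outputs=[str(p) for p in (outputs or [])],
        frozen_parameters=frozen_parameters or {},
    )
    path = out_dir / "manifest.json"
    path.write_text(manifest.to_json())
    return path
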