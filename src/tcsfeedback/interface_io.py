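"""Configuration, fixtures and table serialization.

Parameter sets travel as flat ``key: value`` text files using the
canonical parameter names; survey results as comma-delimited tables with
explicit sentinels (``NA`` for a metric that was not computed, ``inf``
for a response time that was never attained), so that tables stay
machine-checkable and round-trip losslessly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .reaction_network import PARAMETER_NAMES, KineticParameters

__all__ = [
    "FIXTURES",
    "load_fixture",
    "read_parameters",
    "write_parameters",
    "write_survey",
    "read_survey",
    "RunConfig",
    "load_config",
    "write_provenance",
]

FIXTURES = ("negative_example", "positive_example")

#: CSV sentinel for metrics that were not computed (e.g. infeasible set)
NOT_COMPUTED = "NA"


def _parse_kv_text(text: str, source: str) -> dict:
    values = {}
    for ln, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if ":" not in line:
            raise ValueError(f"{source}:{ln}: expected 'key: value', got {raw!r}")
        key, _, val = line.partition(":")
        key = key.strip()
        if key not in PARAMETER_NAMES:
            raise ValueError(f"{source}:{ln}: unknown parameter {key!r}")
        if key in values:
            raise ValueError(f"{source}:{ln}: duplicate parameter {key!r}")
        values[key] = float(val)
    return values


def load_fixture(name: str, **overrides) -> KineticParameters:
    """One of the two bundled example parameter sets.

    ``negative_example`` has open-loop gain < 0 at the activated signal
    (k_ph = 0.1/s), ``positive_example`` > 0.  Keyword overrides set the
    constants the fixture files do not carry (``k_dil``, ``k_ph``,
    ``molecules_per_conc_unit``) or replace stored values.
    """
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {', '.join(FIXTURES)}")
    text = resources.files("tcsfeedback.fixtures").joinpath(f"{name}.txt").read_text()
    values = _parse_kv_text(text, f"fixture {name}")
    values.update(overrides)
    return KineticParameters(**values)


def read_parameters(path, **overrides) -> KineticParameters:
    """Read a flat ``key: value`` parameter file."""
    path = Path(path)
    values = _parse_kv_text(path.read_text(), str(path))
    values.update(overrides)
    return KineticParameters(**values)


def write_parameters(params: KineticParameters, path) -> None:
    """Write a parameter set as a flat ``key: value`` file (full precision)."""
    lines = [f"{name}: {getattr(params, name)!r}" for name in PARAMETER_NAMES]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# survey tables

def write_survey(table: pd.DataFrame, path) -> None:
    """Write a survey table as CSV with explicit sentinels.

    Missing values (metrics not computed) are written as ``NA``;
    infinities (undefined response times / unbounded ratios) as
    ``inf``/``-inf``.  Floats use full repr precision so that
    ``read_survey(write_survey(x)) == x`` field by field.
    """
    table.to_csv(path, index=False, na_rep=NOT_COMPUTED)


def read_survey(path) -> pd.DataFrame:
    """Read a survey table written by :func:`write_survey`."""
    try:
        df = pd.read_csv(path, na_values=[NOT_COMPUTED], keep_default_na=False,
                         float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed survey table {path}: {exc}") from exc
    # booleans serialize as the strings True/False; restore them
    for col in df.columns:
        if df[col].dtype == object:
            vals = set(df[col].dropna().unique())
            if vals and vals <= {"True", "False"}:
                df[col] = df[col].map({"True": True, "False": False})
    return df


# ---------------------------------------------------------------------------
# run configuration

_KNOWN_KEYS = {
    "fixture", "parameter_file", "intervals", "topology", "protocol",
    "metrics", "output_dir", "seed", "n_sets", "k_dil",
    "molecules_per_conc_unit", "rest_k_ph", "act_k_ph", "tolerances",
    "ga", "scan",
}


@dataclass
class RunConfig:
    """Declarative description of one pipeline run.

    The parameter source is exactly one of ``fixture`` (a bundled set
    name), ``parameter_file`` (path to a key:value file) or ``intervals``
    (per-parameter log-uniform sampling bounds, ``{name: [low, high]}``).
    """

    fixture: Optional[str] = None
    parameter_file: Optional[str] = None
    intervals: Optional[dict] = None
    topology: str = "wild_type"
    protocol: list = field(default_factory=list)
    metrics: list = field(default_factory=lambda: ["gain", "flux_fraction", "overshoot"])
    output_dir: str = "results"
    seed: int = 0
    n_sets: int = 100
    k_dil: float = 1.0e-3
    molecules_per_conc_unit: float = 1000.0
    rest_k_ph: float = 10.0
    act_k_ph: float = 0.1
    tolerances: dict = field(default_factory=dict)
    ga: dict = field(default_factory=dict)
    scan: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        sources = [s for s in (self.fixture, self.parameter_file, self.intervals) if s]
        if len(sources) > 1:
            raise ValueError("give at most one parameter source "
                             "(fixture | parameter_file | intervals)")

    def resolve_parameters(self) -> Optional[KineticParameters]:
        """The configured fixed parameter set, or None for sampling runs."""
        fixed = dict(k_dil=self.k_dil,
                     molecules_per_conc_unit=self.molecules_per_conc_unit)
        if self.fixture:
            return load_fixture(self.fixture, **fixed)
        if self.parameter_file:
            return read_parameters(self.parameter_file, **fixed)
        return None


def load_config(path) -> RunConfig:
    """Load a YAML run configuration, rejecting unknown keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a mapping")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def write_provenance(out_dir, seed: int, config_path=None, extra: Optional[dict] = None) -> Path:
    """Record seed, package version and config hash next to the outputs."""
    from . import __version__

    record = {"seed": int(seed), "version": __version__}
    if config_path is not None:
        digest = hashlib.sha256(Path(config_path).read_bytes()).hexdigest()
        record["config"] = str(config_path)
        record["config_sha256"] = digest
    if extra:
        record.update(extra)
    out = Path(out_dir) / "provenance.json"
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")
    return out
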