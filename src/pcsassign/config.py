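"""Run configuration: one structured YAML file drives every pipeline stage.

A run configuration names the structure, declares the datasets (tag site,
lanthanide, labeled subunit, nuclei, peak-list files), and collects the
stage parameters (pairing windows, tolerances, blanking radii, margin
threshold, Monte-Carlo settings, seeds).  Validation rejects unknown keys
and reports every violation at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "DatasetSpec", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Raised with the full list of configuration violations."""


_TOP_KEYS = {
    "structure",
    "model",
    "datasets",
    "output_dir",
    "seed",
    "pairing",
    "tolerances",
    "blanking_radius",
    "margin_threshold",
    "monte_carlo",
    "subunits",
    "free_reference",
    "simulation",
}
_DATASET_KEYS = {
    "id",
    "tag_site",
    "lanthanide",
    "labeled_subunit",
    "nuclei",
    "condition",
    "tagged_peaks",
    "untagged_peaks",
    "stereospecific",
}


@dataclass
class DatasetSpec:
    dataset_id: str
    tag_site: str
    lanthanide: str
    labeled_subunit: str
    nuclei: tuple = ("H", "C")
    condition: str = ""
    tagged_peaks: str = ""
    untagged_peaks: str = ""
    stereospecific: str | None = None


@dataclass
class RunConfig:
    structure: str = ""
    model: int = 1
    datasets: list = field(default_factory=list)
    output_dir: str = "pcs_run"
    seed: int = 0
    pairing: dict = field(default_factory=dict)
    tolerances: dict = field(default_factory=lambda: {"H": 0.008, "C": 0.05})
    blanking_radius: dict = field(default_factory=lambda: {"Dy": 20.0, "Yb": 9.0})
    margin_threshold: float = 9.0
    monte_carlo: dict = field(default_factory=lambda: {"n_samples": 100, "omit_fraction": 0.2})
    subunits: dict = field(default_factory=dict)  # chain -> subunit label
    free_reference: dict = field(default_factory=dict)  # subunit -> peak list path
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    All violations are collected and reported together.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    errors = []
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        errors.append(f"unknown keys: {sorted(unknown)}")

    datasets = []
    for i, d in enumerate(raw.get("datasets", []) or []):
        bad = set(d) - _DATASET_KEYS
        if bad:
            errors.append(f"datasets[{i}]: unknown keys {sorted(bad)}")
        for req in ("id", "tag_site", "lanthanide", "labeled_subunit"):
            if req not in d:
                errors.append(f"datasets[{i}]: missing required key {req!r}")
        nuclei = tuple(d.get("nuclei", ("H", "C")))
        if not nuclei:
            errors.append(f"datasets[{i}]: nuclei must be non-empty")
        for nuc in nuclei:
            if nuc not in ("H", "C"):
                errors.append(f"datasets[{i}]: unknown nucleus {nuc!r}")
        if d.get("stereospecific") not in (None, "pro-R", "pro-S"):
            errors.append(f"datasets[{i}]: stereospecific must be pro-R or pro-S")
        if not errors:
            datasets.append(
                DatasetSpec(
                    dataset_id=str(d["id"]),
                    tag_site=str(d["tag_site"]),
                    lanthanide=str(d["lanthanide"]),
                    labeled_subunit=str(d["labeled_subunit"]),
                    nuclei=nuclei,
                    condition=str(d.get("condition", "")),
                    tagged_peaks=str(d.get("tagged_peaks", "")),
                    untagged_peaks=str(d.get("untagged_peaks", "")),
                    stereospecific=d.get("stereospecific"),
                )
            )
    seen = [d.dataset_id for d in datasets]
    if len(seen) != len(set(seen)):
        errors.append("duplicate dataset ids")

    tol = raw.get("tolerances", {}) or {}
    for nuc, v in tol.items():
        if nuc not in ("H", "C") or not isinstance(v, (int, float)) or v <= 0:
            errors.append(f"tolerances: invalid entry {nuc!r}: {v!r}")
    for lan, v in (raw.get("blanking_radius", {}) or {}).items():
        if not isinstance(v, (int, float)) or v < 0:
            errors.append(f"blanking_radius[{lan}] must be >= 0")

    if errors:
        raise ConfigError(f"{path}: " + "; ".join(errors))

    cfg = RunConfig(
        structure=str(raw.get("structure", "")),
        model=int(raw.get("model", 1)),
        datasets=datasets,
        output_dir=str(raw.get("output_dir", "pcs_run")),
        seed=int(raw.get("seed", 0)),
        pairing=raw.get("pairing", {}) or {},
        margin_threshold=float(raw.get("margin_threshold", 9.0)),
        subunits=raw.get("subunits", {}) or {},
        free_reference=raw.get("free_reference", {}) or {},
        simulation=raw.get("simulation", {}) or {},
    )
    cfg.tolerances.update(tol)
    cfg.blanking_radius.update(raw.get("blanking_radius", {}) or {})
    cfg.monte_carlo.update(raw.get("monte_carlo", {}) or {})
    return cfg
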