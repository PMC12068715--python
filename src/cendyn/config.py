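"""Pipeline configuration: a flat YAML file with one section per stage.

``validate_config`` resolves defaults, checks every referenced file and
parameter, and reports *all* problems at once.  The normalised form
round-trips losslessly through :func:`write_config`.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional, Union

import yaml

from .intervals import GenomicInterval

__all__ = ["PipelineConfig", "ConfigError", "validate_config", "write_config", "parse_region"]

#: documented defaults for every tunable parameter
DEFAULT_PARAMS: Dict[str, Any] = {
    "dmw_window": 5_000,        # bp, differential-modification windows
    "density_window": 200_000,  # bp, motif-density windows
    "profile_box": 1_000_000,   # bp, pericentromere boxes
    "flank": 5_000_000,         # bp, pericentromere extent per side
    "fc_threshold": 4.0,        # ChIP/Input fold for domain calling
    "min_width": 50_000,        # bp, minimum domain width
    "merge_gap": 100_000,       # bp, domain merge gap
    "pseudocount": 1.0,         # reads, enrichment pseudocount
    "dmw_fc": 1.5,              # DMW fold-change threshold
    "dmw_alpha": 0.05,          # DMW BH-adjusted p threshold
    "n_perm": 1000,             # permutation-test draws
    "energy_window": 300,       # nt, stability window
    "energy_step": 150,         # nt, stability step
    "pc1_resolution": 50_000,   # bp, compartment matrix resolution
    "tad_resolution": 20_000,   # bp, TAD matrix resolution
    "insulation_window": 10,    # bins
    "tad_delta": 0.1,           # insulation prominence
    "tad_significance": 0.01,   # boundary FDR
    "boundary_slack": 2,        # bins, boundary matching
    "left_is_short_arm": True,  # arm orientation of the segment
}

_POSITIVE = {
    "dmw_window", "density_window", "profile_box", "flank", "fc_threshold",
    "min_width", "merge_gap", "dmw_fc", "dmw_alpha", "n_perm",
    "energy_window", "energy_step", "pc1_resolution", "tad_resolution",
    "insulation_window", "tad_delta", "tad_significance",
}


class ConfigError(ValueError):
    """Raised with every configuration problem listed at once."""

    def __init__(self, problems: List[str]):
        self.problems = problems
        super().__init__("invalid configuration:\n  " + "\n  ".join(problems))


def parse_region(text: str) -> GenomicInterval:
    """Parse ``chrom:start-end`` (bp, 0-based half-open)."""
    chrom, span = text.split(":")
    start, end = span.replace(",", "").split("-")
    return GenomicInterval(chrom, int(start), int(end))


@dataclass
class PipelineConfig:
    """Fully resolved pipeline configuration."""

    genome: Optional[str] = None
    tracks: List[Dict[str, Any]] = field(default_factory=list)
    contacts: Dict[str, Dict[str, str]] = field(default_factory=dict)
    annotations: Optional[str] = None
    centromere: Optional[str] = None  # declared parent centromere, chrom:start-end
    params: Dict[str, Any] = field(default_factory=lambda: copy.deepcopy(DEFAULT_PARAMS))
    seed: int = 0
    outdir: str = "cendyn_out"

    def to_dict(self) -> Dict[str, Any]:
        return {
            "genome": self.genome,
            "tracks": self.tracks,
            "contacts": self.contacts,
            "annotations": self.annotations,
            "centromere": self.centromere,
            "params": dict(self.params),
            "seed": self.seed,
            "outdir": self.outdir,
        }


def validate_config(path: Union[str, Path]) -> PipelineConfig:
    """Read, default-fill and validate a YAML config; every problem reported."""
    path = Path(path)
    problems: List[str] = []
    if not path.exists():
        raise ConfigError([f"config file not found: {path}"])
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigError([f"config not parseable: {exc}"])
    if not isinstance(raw, dict):
        raise ConfigError(["config must be a mapping"])

    known = {"genome", "tracks", "contacts", "annotations", "centromere", "params", "seed", "outdir"}
    for key in raw:
        if key not in known:
            problems.append(f"unknown section {key!r}")

    params = copy.deepcopy(DEFAULT_PARAMS)
    for k, v in (raw.get("params") or {}).items():
        if k not in DEFAULT_PARAMS:
            problems.append(f"unknown parameter {k!r}")
            continue
        if k in _POSITIVE and (not isinstance(v, (int, float)) or v <= 0):
            problems.append(f"parameter {k!r} must be positive, got {v!r}")
            continue
        params[k] = v

    base = path.parent

    def _resolve(p: Optional[str], what: str) -> Optional[str]:
        if p is None:
            return None
        full = Path(p) if Path(p).is_absolute() else base / p
        if not full.exists():
            problems.append(f"{what} file not found: {p}")
        return str(full)

    genome = _resolve(raw.get("genome"), "genome")
    annotations = _resolve(raw.get("annotations"), "annotations")

    tracks = []
    for i, t in enumerate(raw.get("tracks") or []):
        if not isinstance(t, dict) or not {"sample", "mark", "chip", "input"} <= set(t):
            problems.append(f"track {i}: needs sample, mark, chip, input")
            continue
        t = dict(t)
        t.setdefault("replicate", 0)
        t["chip"] = _resolve(t["chip"], f"track {i} chip")
        t["input"] = _resolve(t["input"], f"track {i} input")
        for key in ("chip_library", "input_library"):
            if key in t and (not isinstance(t[key], (int, float)) or t[key] <= 0):
                problems.append(f"track {i}: {key} must be a positive number")
        tracks.append(t)

    contacts = {}
    for sample, entry in (raw.get("contacts") or {}).items():
        if not isinstance(entry, dict) or "path" not in entry:
            problems.append(f"contacts.{sample}: needs path (triplet TSV)")
            continue
        contacts[sample] = {
            "path": _resolve(entry["path"], f"contacts.{sample}"),
            "n_bins": entry.get("n_bins"),
        }

    centromere = raw.get("centromere")
    if centromere is not None:
        try:
            parse_region(str(centromere))
        except Exception:
            problems.append(f"centromere must be chrom:start-end, got {centromere!r}")

    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        problems.append(f"seed must be an integer, got {seed!r}")
        seed = 0

    if problems:
        raise ConfigError(problems)
    return PipelineConfig(
        genome=genome, tracks=tracks, contacts=contacts, annotations=annotations,
        centromere=centromere, params=params, seed=seed,
        outdir=str(raw.get("outdir", "cendyn_out")),
    )


def write_config(config: PipelineConfig, path: Union[str, Path]) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
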