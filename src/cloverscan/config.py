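"""Typed configuration records: every tunable threshold in one place.

Defaults are the pipeline's published operating points: a 10-bit first-pass
cutoff feeding a 20-bit structural reporting threshold; the 55/10/5
pseudogene rule; the 70/50/10 secondary high-confidence stage; the dynamic
71->95-bit tertiary stage capping each anticodon at 40 predictions; 60-nt
flanks and a 70-nt minimum mature length for noncanonical intron search;
10/15-nt position tolerances for nuclear/mitochondrial comparisons.
"""

from __future__ import annotations

import configparser
import warnings
from dataclasses import dataclass, field, fields

from .records import FormatError


@dataclass
class ScanConfig:
    first_pass_cutoff: float = 10.0   # bits
    report_cutoff: float = 20.0       # bits
    candidate_flank: int = 60         # nt added each side of first-pass windows
    max_mode_window: int = 200        # nt, exhaustive single-pass sliding window
    max_mode_overlap: int = 150       # nt overlap between adjacent windows

    def __post_init__(self) -> None:
        if self.first_pass_cutoff > self.report_cutoff:
            raise ValueError("first_pass_cutoff must be <= report_cutoff")
        if self.candidate_flank < 0:
            raise ValueError("candidate_flank must be >= 0")
        if self.max_mode_overlap >= self.max_mode_window:
            raise ValueError("max_mode_overlap must be < max_mode_window")


@dataclass
class FilterConfig:
    pseudo_overall: float = 55.0
    pseudo_primary: float = 10.0
    pseudo_secondary: float = 5.0
    stage2_isotype: float = 70.0
    stage2_overall: float = 50.0
    stage2_secondary: float = 10.0
    stage3_start: float = 71.0
    stage3_cap: float = 95.0
    stage3_max_per_anticodon: int = 40

    def __post_init__(self) -> None:
        if self.stage3_start > self.stage3_cap:
            raise ValueError("stage3_start must be <= stage3_cap")


@dataclass
class IntronConfig:
    flank: int = 60               # nt of flanking sequence added before BHB search
    min_mature_len: int = 70      # nt; iteration stops below this mature length
    bhb_accept_bits: float = 10.0
    min_intron_len: int = 8
    max_iterations: int = 3
    bhb_span_slack: int = 10      # nt a BHB hit may exceed its model span;
                                  # an interrupted motif is not a formed BHB

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be positive")


@dataclass
class CompareConfig:
    nuclear_tolerance: int = 10   # nt
    mito_tolerance: int = 15      # nt

    def __post_init__(self) -> None:
        if self.nuclear_tolerance < 0 or self.mito_tolerance < 0:
            raise ValueError("tolerances must be >= 0")


@dataclass
class ToolConfig:
    """Aggregate configuration plus model-registry paths."""

    scan: ScanConfig = field(default_factory=ScanConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    introns: IntronConfig = field(default_factory=IntronConfig)
    compare: CompareConfig = field(default_factory=CompareConfig)
    alternate_models: list = field(default_factory=list)
    model_dir: str = ""


_SECTIONS = {
    "scan": ScanConfig,
    "filters": FilterConfig,
    "introns": IntronConfig,
    "compare": CompareConfig,
}


def read_config(path) -> ToolConfig:
    """Read an INI-style key-value config file.

    Every omitted threshold takes its default; unknown keys warn but do not
    fail; non-numeric threshold values raise :class:`FormatError`.  The
    ``[models]`` section may carry ``dir`` and ``alternate`` (one path per
    whitespace/comma-separated entry, order preserved).
    """
    parser = configparser.ConfigParser()
    read = parser.read(str(path))
    if not read:
        raise FormatError(f"config file not found: {path}")

    cfg = ToolConfig()
    for section in parser.sections():
        if section == "models":
            for key, value in parser.items(section):
                if key == "dir":
                    cfg.model_dir = value.strip()
                elif key == "alternate":
                    cfg.alternate_models = [
                        p for p in value.replace(",", " ").split() if p
                    ]
                else:
                    warnings.warn(f"config: unknown key [models] {key}")
            continue
        cls = _SECTIONS.get(section)
        if cls is None:
            warnings.warn(f"config: unknown section [{section}]")
            continue
        known = {f.name: f.type for f in fields(cls)}
        kwargs = {}
        for key, value in parser.items(section):
            if key not in known:
                warnings.warn(f"config: unknown key [{section}] {key}")
                continue
            try:
                kwargs[key] = (
                    int(value) if known[key] == "int" else float(value)
                )
            except ValueError as exc:
                raise FormatError(
                    f"config: non-numeric value for [{section}] {key}: {value!r}"
                ) from exc
        setattr(cfg, section, cls(**kwargs))
    return cfg
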