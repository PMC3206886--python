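"""Configuration objects shared across the pipeline.

Two dataclasses define everything a run needs: :class:`CohortConfig`
parameterizes the synthetic-cohort generator and :class:`PipelineConfig`
parameterizes the analysis itself (sparsity sweep, null-ensemble size,
statistical flags).  Both validate eagerly on construction and serialize to
plain dictionaries so that a run can echo its exact configuration to disk.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "AAL90_LABELS",
    "CohortConfig",
    "PipelineConfig",
    "config_hash",
]

# The 45 bilateral cortical/subcortical region abbreviations of the 90-region
# AAL parcellation.  Each is expanded to a left/right pair below; the
# interleaved L/R ordering is a package convention (any consistent ordering is
# equivalent for the analysis, which is permutation-invariant).
_AAL_BILATERAL = [
    "SFGdor", "ORBsup", "SFGmed", "ORBsupmed", "MFG", "ORBmid", "IFGoperc",
    "IFGtriang", "ORBinf", "REC", "ACG", "OLF", "SPL", "PCL", "PoCG", "IPL",
    "SMG", "ANG", "PCUN", "PCG", "PreCG", "SMA", "MCG", "STG", "TPOsup",
    "MTG", "TPOmid", "ITG", "HES", "HIP", "PHG", "AMYG", "INS", "THA", "CAU",
    "PUT", "PAL", "CAL", "CUN", "LING", "SOG", "MOG", "IOG", "FFG", "ROL",
]

#: Canonical 90-region label list, left/right interleaved ("SFGdor.L",
#: "SFGdor.R", ...).
AAL90_LABELS: tuple[str, ...] = tuple(
    f"{abbr}.{hemi}" for abbr in _AAL_BILATERAL for hemi in ("L", "R")
)


class ConfigurationError(ValueError):
    """Raised when a configuration object fails validation."""


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic resting-state cohort.

    The defaults emulate the study design the analysis targets: a 2x2
    sex-by-disease cohort of 20 females and 18 males per group, 90 regions,
    205 volumes at TR = 2 s, with a modular (block) correlation structure
    perturbed by disease, by a sex-by-disease interaction, and by each
    patient's disease duration.

    Parameters
    ----------
    n_females_per_group, n_males_per_group
        Cell sizes of the sex x disease design (same counts in the patient
        and the control group).
    n_regions, n_timepoints, tr_seconds
        Dimensions of each subject's region x time matrix and its sampling
        interval in seconds.
    n_modules
        Number of communities in the block correlation structure.
    within_module_r, between_module_r
        Target Pearson correlation inside / between communities.
    disease_effect
        Additive *reduction* of within-module coupling on the affected
        regions, applied to every patient.
    sex_disease_interaction
        Extra coupling reduction applied only to female patients (the
        interaction cell of the 2x2 design).
    duration_slope
        Linear coefficient (correlation units per year) linking a patient's
        disease duration, centered at the population mean, to their coupling
        perturbation.  A positive slope makes longer-duration patients more
        strongly coupled, which downstream appears as a positive
        age-controlled partial correlation with small-worldness.
    affected_regions
        Indices of the regions whose within-module couplings carry the
        disease/interaction/duration perturbations.  ``None`` selects the
        first module.
    noise_ar1
        Lag-1 autocorrelation of the regional noise process.
    nuisance_amplitude
        Standard deviation of the nuisance contribution mixed into each
        region's signal, relative to the unit-variance neural signal.
    seed
        Base seed; identical seed and config give a bit-identical cohort.
    """

    n_females_per_group: int = 20
    n_males_per_group: int = 18
    n_regions: int = 90
    n_timepoints: int = 205
    tr_seconds: float = 2.0
    n_modules: int = 5
    within_module_r: float = 0.5
    between_module_r: float = 0.1
    disease_effect: float = 0.05
    sex_disease_interaction: float = 0.05
    duration_slope: float = 0.005
    affected_regions: tuple[int, ...] | None = None
    noise_ar1: float = 0.3
    nuisance_amplitude: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("within_module_r", "between_module_r"):
            v = getattr(self, name)
            if not -1.0 < v < 1.0:
                raise ConfigurationError(f"{name}={v} must lie in (-1, 1)")
        if self.within_module_r <= self.between_module_r:
            raise ConfigurationError(
                "within_module_r must exceed between_module_r "
                f"({self.within_module_r} <= {self.between_module_r})"
            )
        if self.n_timepoints < 30:
            raise ConfigurationError(
                "n_timepoints must be >= 30 for correlation estimability"
            )
        if not 1 <= self.n_modules <= self.n_regions:
            raise ConfigurationError("n_modules must be in [1, n_regions]")
        if self.n_females_per_group < 0 or self.n_males_per_group < 0:
            raise ConfigurationError("cell counts must be non-negative")
        if self.n_females_per_group + self.n_males_per_group == 0:
            raise ConfigurationError("cohort must contain at least one subject")
        if not 0.0 <= self.noise_ar1 < 1.0:
            raise ConfigurationError("noise_ar1 must lie in [0, 1)")
        if self.tr_seconds <= 0:
            raise ConfigurationError("tr_seconds must be positive")
        if self.affected_regions is not None:
            idx = tuple(int(i) for i in self.affected_regions)
            if any(i < 0 or i >= self.n_regions for i in idx):
                raise ConfigurationError("affected_regions index out of range")
            object.__setattr__(self, "affected_regions", idx)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["affected_regions"] is not None:
            d["affected_regions"] = list(d["affected_regions"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown CohortConfig keys: {sorted(unknown)}")
        d = dict(d)
        if d.get("affected_regions") is not None:
            d["affected_regions"] = tuple(d["affected_regions"])
        return cls(**d)


@dataclass(frozen=True)
class PipelineConfig:
    """Parameters of the analysis pipeline.

    Numeric defaults follow the analysis design: band-pass 0.01-0.08 Hz,
    motion limits 1.5 mm / 1.5 degrees, sparsity sweep 0.15-0.25 in 0.01
    steps with S = 0.15 as the reference density, 100-graph null ensembles,
    and FDR control at q = 0.05.
    """

    sparsity_low: float = 0.15
    sparsity_high: float = 0.25
    sparsity_step: float = 0.01
    analysis_sparsity: float = 0.15
    bandpass_low_hz: float = 0.01
    bandpass_high_hz: float = 0.08
    displacement_limit_mm: float = 1.5
    rotation_limit_deg: float = 1.5
    n_random: int = 100
    swaps_per_edge: int = 10
    fdr_q: float = 0.05
    threshold_mode: str = "signed"      # "signed" or "absolute" ranking
    ss_type: int = 2                    # ANOVA sums-of-squares type (2 or 3)
    fdr_method: str = "bh"              # "bh" or "by"
    attack_recompute: bool = False      # recompute centrality after removals
    edge_stats: bool = False            # edge-level Fisher-z ANOVA over all pairs
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.sparsity_low <= self.sparsity_high <= 1:
            raise ConfigurationError(
                f"invalid sparsity range [{self.sparsity_low}, {self.sparsity_high}]"
            )
        if self.sparsity_step <= 0:
            raise ConfigurationError("sparsity_step must be positive")
        if not 0 < self.analysis_sparsity <= 1:
            raise ConfigurationError("analysis_sparsity must lie in (0, 1]")
        if not 0 < self.bandpass_low_hz < self.bandpass_high_hz:
            raise ConfigurationError("require 0 < bandpass_low_hz < bandpass_high_hz")
        if self.n_random < 1:
            raise ConfigurationError("n_random must be >= 1")
        if self.threshold_mode not in ("signed", "absolute"):
            raise ConfigurationError("threshold_mode must be 'signed' or 'absolute'")
        if self.ss_type not in (2, 3):
            raise ConfigurationError("ss_type must be 2 or 3")
        if self.fdr_method not in ("bh", "by"):
            raise ConfigurationError("fdr_method must be 'bh' or 'by'")
        if not 0 < self.fdr_q < 1:
            raise ConfigurationError("fdr_q must lie in (0, 1)")

    @property
    def sparsities(self) -> tuple[float, ...]:
        """Inclusive sweep grid, rounded to suppress float accumulation."""
        out = []
        s = self.sparsity_low
        while s <= self.sparsity_high + 1e-9:
            out.append(round(s, 10))
            s += self.sparsity_step
        return tuple(out)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown PipelineConfig keys: {sorted(unknown)}")
        return cls(**d)


def config_hash(*configs) -> str:
    """Short stable hash of one or more config objects (for output headers)."""
    payload = json.dumps(
        [c.to_dict() for c in configs], sort_keys=True, separators=(",", ":")
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
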