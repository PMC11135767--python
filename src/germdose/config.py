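"""Simulation configuration and shared chromosome / stage vocabulary.

The package models the male germline of a species carrying X chromosome arms
of three evolutionary ages (an ancestral X ``MullerA``, an intermediate-age
fused arm ``MullerAD``, a young neo-X ``MullerC``), a degenerating male-limited
``neoY``, the autosomal reference arms ``MullerB`` and ``MullerE``, and the
small ``MullerF`` dot chromosome (a former X, excluded from autosomal
references).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

#: Closed set of chromosome classes used throughout the package.
CHROMOSOME_CLASSES = (
    "MullerA", "MullerAD", "MullerC", "neoY", "MullerB", "MullerE", "MullerF", "other",
)

#: X-linked chromosome arms, ordered oldest -> youngest.
X_CHROMOSOMES = ("MullerA", "MullerAD", "MullerC")

#: Autosomal arms anchoring X:A ratios and the modified-TPM normalizer.
REFERENCE_AUTOSOMES = ("MullerB", "MullerE")

#: Ordered spermatogenesis cell types: somatic support cells (hub, cyst),
#: germline stem cells, spermatogonia, spermatocytes, early spermatids.
DEFAULT_STAGES = (
    "hub", "cyst", "GSC", "SG", "SC_early", "SC_late1", "SC_late2", "ST_early",
)

#: Stages treated as meiotic, where MSCI or DC shutdown would act.
DEFAULT_MEIOTIC_STAGES = ("SC_late1", "SC_late2", "ST_early")

#: Germline stages (somatic hub/cyst excluded), ordered along spermatogenesis.
DEFAULT_GERMLINE_STAGES = ("GSC", "SG", "SC_early", "SC_late1", "SC_late2", "ST_early")

#: Dosage-compensation machinery genes summarized by dc_gene_summary.
DC_MACHINERY_GENES = (
    "msl-1", "msl-2", "msl-3", "mle", "mof", "roX1", "roX2", "clamp", "mtor",
)

REGIMES = ("DC_SHUTDOWN", "MSCI", "NONE")


class SimConfigError(ValueError):
    """Raised when a simulation configuration violates an invariant."""


def _default_genes() -> dict:
    # Muller elements carry ~2,500-3,000 genes each; the degenerating neo-Y
    # retains an expressed subset, and the dot chromosome is tiny.
    return {
        "MullerA": 2500,
        "MullerAD": 2700,
        "MullerC": 2800,
        "neoY": 1100,
        "MullerB": 2800,
        "MullerE": 2800,
        "MullerF": 80,
    }


def _default_cells() -> dict:
    return {stage: 300 for stage in DEFAULT_STAGES}


def _default_boost() -> dict:
    # Full compensation on the ancestral X, intermediate on the fused arm,
    # partial on the young neo-X; autosomes and the neo-Y are uncompensated.
    return {
        "MullerA": 2.0,
        "MullerAD": 1.6,
        "MullerC": 1.2,
        "neoY": 1.0,
        "MullerB": 1.0,
        "MullerE": 1.0,
        "MullerF": 1.0,
    }


def _default_copy_number() -> dict:
    return {
        "MullerA": 1,
        "MullerAD": 1,
        "MullerC": 1,
        "neoY": 1,
        "MullerB": 2,
        "MullerE": 2,
        "MullerF": 2,
    }


@dataclass
class SimConfig:
    """Ground-truth parameters of the synthetic testis / two-species generator.

    Expression of gene ``g`` in a cell of stage ``t`` has expectation

        mu[g, t] = B_g * A_t * (CN_g / 2) * D[g, t] * S[g, t] * gamma_g

    with per-gene lognormal baseline ``B_g``, stage-wise global amplification
    ``A_t`` (peaking in late spermatocytes), copy number ``CN_g``,
    MSL-distance-decaying dosage-compensation boost
    ``D = 1 + (boost_max - 1) * profile_t * exp(-d_g / lambda)``,
    meiotic silencing ``S`` (``msci_factor`` on X arms in meiotic stages under
    an MSCI regime, else 1), and neo-Y retention ``gamma_g`` (< 1 only on the
    neo-Y). Counts are negative binomial around ``mu`` scaled by a lognormal
    per-cell library-size factor.
    """

    seed: int = 0
    stages: Sequence[str] = DEFAULT_STAGES
    meiotic_stages: Sequence[str] = DEFAULT_MEIOTIC_STAGES
    n_genes_per_chrom: Mapping[str, int] = field(default_factory=_default_genes)
    n_cells_per_type: Mapping[str, int] = field(default_factory=_default_cells)

    # lognormal baseline B_g (natural-log parameters)
    baseline_logmean: float = 1.0
    baseline_logsd: float = 1.0

    # global transcriptional amplification per stage, peaking in late SC
    stage_amplification: Sequence[float] = (1.0, 1.0, 1.0, 1.3, 2.0, 4.0, 4.0, 3.0)

    copy_number: Mapping[str, int] = field(default_factory=_default_copy_number)

    # dosage compensation
    dc_boost_max: Mapping[str, float] = field(default_factory=_default_boost)
    dc_distance_scale: float = 10_000.0  # bp decay constant of the boost
    #: Per-stage multiplier in [0,1] scaling compensation. None = derived from
    #: the regime at simulation time (shutdown: declines to 0 across the
    #: meiotic stages; otherwise all ones).
    dc_stage_profile: Sequence[float] | None = None
    #: Per-tissue multiplier for bulk simulations; tissues absent default to 1.
    dc_tissue_profile: Mapping[str, float] = field(
        default_factory=lambda: {"testis": 0.5}
    )

    # meiotic silencing under an MSCI regime
    msci_factor: float = 0.4

    # neo-Y degeneration: gamma_g = sigmoid(Normal(mean, sd))
    y_degeneration_logitmean: float = 0.0
    y_degeneration_logitsd: float = 1.0

    # counting noise
    nb_dispersion: float = 0.1
    libsize_logmean: float = 0.0
    libsize_logsd: float = 0.3

    # gene / peak geometry
    gene_len_range: tuple = (1_000, 3_000)
    intergenic_mean: float = 3_000.0
    peak_density: float = 50.0  # MSL peaks per Mb on X-linked arms
    peak_width: int = 500
    peak_bias: float = 1.0  # preference for placing peaks near high-B genes

    # bulk two-species measurement noise (natural-log sd, multiplicative)
    bulk_noise_logsd: float = 0.2

    # CDS trio generator
    n_trios: int = 200
    trio_cds_len_range: tuple = (150, 600)
    trio_mutation_rate: float = 0.05
    x_loss_prob: float = 0.05
    y_loss_prob: float = 0.15
    y_truncation_prob: float = 0.3
    y_truncation_range: tuple = (0.25, 0.6)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for chrom in self.n_genes_per_chrom:
            if chrom not in CHROMOSOME_CLASSES:
                raise SimConfigError(f"unknown chromosome class: {chrom!r}")
        for chrom, n in self.n_genes_per_chrom.items():
            if n <= 0:
                raise SimConfigError(f"n_genes_per_chrom[{chrom!r}] must be > 0")
        for stage, n in self.n_cells_per_type.items():
            if stage not in self.stages:
                raise SimConfigError(f"cell-count stage {stage!r} not in stage list")
            if n <= 0:
                raise SimConfigError(f"n_cells_per_type[{stage!r}] must be > 0")
        for stage in self.meiotic_stages:
            if stage not in self.stages:
                raise SimConfigError(f"meiotic stage {stage!r} not in stage list")
        if len(self.stage_amplification) != len(self.stages):
            raise SimConfigError("stage_amplification length != number of stages")
        if any(a < 0 for a in self.stage_amplification):
            raise SimConfigError("stage_amplification entries must be >= 0")
        if self.dc_stage_profile is not None:
            if len(self.dc_stage_profile) != len(self.stages):
                raise SimConfigError("dc_stage_profile length != number of stages")
            if any(not (0.0 <= p <= 1.0) for p in self.dc_stage_profile):
                raise SimConfigError("dc_stage_profile entries must be in [0, 1]")
        for chrom, b in self.dc_boost_max.items():
            if not (1.0 <= b <= 2.0):
                raise SimConfigError(f"dc_boost_max[{chrom!r}] must be in [1, 2]")
        for chrom, cn in self.copy_number.items():
            if cn not in (1, 2):
                raise SimConfigError(f"copy_number[{chrom!r}] must be 1 or 2")
        if not (0.0 < self.msci_factor <= 1.0):
            raise SimConfigError("msci_factor must be in (0, 1]")
        if self.nb_dispersion <= 0:
            raise SimConfigError("nb_dispersion must be > 0")
        if not (0.0 <= self.trio_mutation_rate <= 0.25):
            raise SimConfigError("trio_mutation_rate must be in [0, 0.25]")
        for name in ("x_loss_prob", "y_loss_prob", "y_truncation_prob"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise SimConfigError(f"{name} must be in [0, 1]")

    def replace(self, **changes) -> "SimConfig":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def stage_index(self, stage: str) -> int:
        return list(self.stages).index(stage)

    # -- YAML round-trip ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("stages", "meiotic_stages", "stage_amplification",
                    "gene_len_range", "trio_cds_len_range", "y_truncation_range"):
            if d[key] is not None:
                d[key] = list(d[key])
        if d["dc_stage_profile"] is not None:
            d["dc_stage_profile"] = list(d["dc_stage_profile"])
        for key in ("n_genes_per_chrom", "n_cells_per_type", "copy_number",
                    "dc_boost_max", "dc_tissue_profile"):
            d[key] = dict(d[key])
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        for key in ("stages", "meiotic_stages", "stage_amplification",
                    "gene_len_range", "trio_cds_len_range", "y_truncation_range",
                    "dc_stage_profile"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def shutdown_stage_profile(config: SimConfig) -> tuple:
    """Compensation profile declining linearly to 0 across the meiotic stages.

    Pre-meiotic stages keep full compensation (1); the k-th of K meiotic
    stages gets 1 - (k+1)/K, so the final stage is fully shut down (0).
    """
    meiotic = [s for s in config.stages if s in config.meiotic_stages]
    K = len(meiotic)
    profile = []
    for stage in config.stages:
        if stage in config.meiotic_stages:
            k = meiotic.index(stage)
            profile.append(1.0 - (k + 1) / K)
        else:
            profile.append(1.0)
    return tuple(profile)


def effective_stage_profile(config: SimConfig, regime: str) -> tuple:
    """Resolve the compensation stage profile for a regime.

    An explicitly configured profile wins; otherwise DC_SHUTDOWN derives a
    declining profile and MSCI / NONE keep compensation on at every stage.
    """
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}; expected one of {REGIMES}")
    if config.dc_stage_profile is not None:
        return tuple(config.dc_stage_profile)
    if regime == "DC_SHUTDOWN":
        return shutdown_stage_profile(config)
    return tuple(1.0 for _ in config.stages)
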