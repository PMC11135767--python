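"""Synthetic data generator with known ground truth.

Emulates the three input classes of a germline dosage-compensation study:

* single-cell UMI counts across ordered spermatogenesis stages, under a
  configurable regulatory regime (DC shutdown, MSCI, or neither);
* bulk expression tables for an ingroup species carrying a neo-X/neo-Y pair
  and an outgroup species where the same Muller element is still autosomal;
* coding-sequence trios (ancestral gene, neo-X descendant, neo-Y descendant)
  for exercising reciprocal-best-hit gametolog calling.

Every generator records its ground truth (expected expression, true X:A
ratios, true gametolog map, true gene-to-peak distances) so downstream
estimates can be scored against known values.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

from .config import (
    REFERENCE_AUTOSOMES,
    REGIMES,
    X_CHROMOSOMES,
    SimConfig,
    SimConfigError,
    effective_stage_profile,
)
from .mslmap import nearest_peak_distance

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# annotation + peaks
# ---------------------------------------------------------------------------

def make_annotation(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Lay out genes on linear chromosomes and place MSL peaks.

    Returns ``(annotation, peaks)``. The annotation is indexed by gene id with
    columns ``chromosome, start, end, strand, cds_length`` plus ground-truth
    columns ``baseline`` (B_g), ``y_retention`` (gamma_g, 1 except on the
    neo-Y), ``gametolog_of`` (ancestral neo-X partner of each neo-Y gene) and
    ``msl_distance`` (true distance to the nearest peak; NaN where the
    chromosome carries no peak). Peaks are a BED-like frame with columns
    ``chromosome, start, end``; they are placed on X-linked arms only, with
    placement biased toward high-baseline genes when ``peak_bias > 0``.

    Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.gene_len_range

    rows = []
    baselines: dict[str, float] = {}
    for chrom, n in config.n_genes_per_chrom.items():
        cursor = 0
        lengths = rng.integers(lo, hi + 1, size=n)
        gaps = np.maximum(rng.exponential(config.intergenic_mean, size=n), 200.0)
        strands = rng.choice(["+", "-"], size=n)
        b = np.exp(rng.normal(config.baseline_logmean, config.baseline_logsd, size=n))
        for i in range(n):
            start = int(cursor + gaps[i])
            end = start + int(lengths[i])
            gid = f"{chrom}_g{i:04d}"
            cds = max(100, int(lengths[i] * rng.uniform(0.3, 0.9)))
            rows.append((gid, chrom, start, end, strands[i], cds))
            baselines[gid] = b[i]
            cursor = end

    ann = pd.DataFrame(
        rows, columns=["gene_id", "chromosome", "start", "end", "strand", "cds_length"]
    ).set_index("gene_id")
    ann["baseline"] = pd.Series(baselines)

    # neo-Y genes descend from neo-X (MullerC) genes: shared ancestral baseline,
    # multiplied by a per-gene retention factor gamma.
    ann["y_retention"] = 1.0
    ann["gametolog_of"] = pd.Series(dtype=object)
    neoy = ann.index[ann.chromosome == "neoY"]
    neox = ann.index[ann.chromosome == "MullerC"]
    n_pair = min(len(neoy), len(neox))
    if len(neoy) > 0:
        gamma = 1.0 / (1.0 + np.exp(-rng.normal(
            config.y_degeneration_logitmean, config.y_degeneration_logitsd,
            size=len(neoy))))
        ann.loc[neoy, "y_retention"] = gamma
        ann.loc[neoy[:n_pair], "gametolog_of"] = neox[:n_pair]
        ann.loc[neoy[:n_pair], "baseline"] = ann.loc[neox[:n_pair], "baseline"].to_numpy()

    peaks = _place_peaks(config, ann, rng)
    dist = nearest_peak_distance(ann, peaks)
    ann["msl_distance"] = dist["distance_bp"].astype(float)
    return ann, peaks


def _place_peaks(config: SimConfig, ann: pd.DataFrame, rng) -> pd.DataFrame:
    rows = []
    for chrom in config.n_genes_per_chrom:
        if chrom not in X_CHROMOSOMES or config.peak_density <= 0:
            continue
        sub = ann[ann.chromosome == chrom]
        length = int(sub.end.max()) + int(config.intergenic_mean)
        n_peaks = rng.poisson(config.peak_density * length / 1e6)
        if n_peaks == 0:
            continue
        b = sub.baseline.to_numpy()
        w = b / b.sum()
        p_near = config.peak_bias / (1.0 + config.peak_bias)
        for _ in range(n_peaks):
            if rng.random() < p_near:
                g = sub.iloc[rng.choice(len(sub), p=w)]
                pos = int(rng.uniform(g.start - 2000, g.end + 2000))
            else:
                pos = int(rng.uniform(0, length - config.peak_width))
            pos = max(0, min(pos, length - config.peak_width))
            rows.append((chrom, pos, pos + config.peak_width))
    return pd.DataFrame(rows, columns=["chromosome", "start", "end"])


# ---------------------------------------------------------------------------
# ground truth container
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """True expected expression and derived quantities for one simulation."""

    mu: pd.DataFrame                #: genes x stages expected relative expression
    xa: pd.DataFrame                #: chromosomes x stages true X:A ratios
    gametolog_map: pd.DataFrame     #: neoX_id <-> neoY_id true pairing
    msl_distance: pd.Series         #: true gene-to-nearest-peak distance (bp)
    regime: str = "NONE"
    stage_profile: tuple = field(default_factory=tuple)


def _expected_mu(config: SimConfig, annotation: pd.DataFrame, regime: str) -> pd.DataFrame:
    profile = effective_stage_profile(config, regime)
    chrom = annotation.chromosome
    cn = chrom.map(lambda c: config.copy_number.get(c, 2)).to_numpy(float)
    boost = chrom.map(lambda c: config.dc_boost_max.get(c, 1.0)).to_numpy(float)
    dist = annotation.msl_distance.to_numpy(float)
    decay = np.where(np.isfinite(dist), np.exp(-dist / config.dc_distance_scale), 0.0)
    base = annotation.baseline.to_numpy(float)
    gamma = annotation.y_retention.to_numpy(float)
    on_x = chrom.isin(X_CHROMOSOMES).to_numpy()

    mu = np.empty((len(annotation), len(config.stages)))
    for j, stage in enumerate(config.stages):
        d = 1.0 + (boost - 1.0) * profile[j] * decay
        d = np.minimum(d, boost)
        s = np.ones(len(annotation))
        if regime == "MSCI" and stage in config.meiotic_stages:
            s[on_x] = config.msci_factor
        mu[:, j] = base * config.stage_amplification[j] * (cn / 2.0) * d * s * gamma
    return pd.DataFrame(mu, index=annotation.index, columns=list(config.stages))


def _true_xa(mu: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    ref = annotation.index[annotation.chromosome.isin(REFERENCE_AUTOSOMES)]
    ref_median = mu.loc[ref].median(axis=0)
    chroms = annotation.chromosome.unique()
    out = {}
    for chrom in chroms:
        genes = annotation.index[annotation.chromosome == chrom]
        out[chrom] = mu.loc[genes].median(axis=0) / ref_median
    return pd.DataFrame(out).T


def ground_truth_xa(truth: GroundTruth, chromosome: str, stage: str) -> float:
    """Analytically expected chromosome-median X:A ratio under the generator."""
    try:
        return float(truth.xa.loc[chromosome, stage])
    except KeyError as exc:
        raise ValueError(f"unknown chromosome/stage: {exc}") from exc


# ---------------------------------------------------------------------------
# single-cell counts
# ---------------------------------------------------------------------------

def simulate_sc_counts(
    config: SimConfig,
    annotation: pd.DataFrame,
    regime: str = "NONE",
) -> tuple[AnnData, GroundTruth]:
    """Draw a genes-by-cells UMI count matrix under a regulatory regime.

    Counts for a cell of stage t are negative binomial with mean
    ``mu[g, t] * libsize_c`` and shared dispersion. Returns an AnnData
    (cells as obs with ``cell_type`` and ``replicate``; genes as var carrying
    the annotation) together with the :class:`GroundTruth`.
    """
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}; expected one of {REGIMES}")
    missing = set(annotation.chromosome) - set(config.n_genes_per_chrom)
    if missing:
        raise SimConfigError(f"annotation chromosomes not in config: {sorted(missing)}")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    mu = _expected_mu(config, annotation, regime)
    truth = GroundTruth(
        mu=mu,
        xa=_true_xa(mu, annotation),
        gametolog_map=_gametolog_map(annotation),
        msl_distance=annotation.msl_distance.copy(),
        regime=regime,
        stage_profile=effective_stage_profile(config, regime),
    )

    blocks = []
    cell_types = []
    n_genes = len(annotation)
    shape = 1.0 / config.nb_dispersion
    for stage in config.stages:
        n_cells = config.n_cells_per_type.get(stage, 0)
        if n_cells == 0:
            continue
        lib = np.exp(rng.normal(config.libsize_logmean, config.libsize_logsd, n_cells))
        m = mu[stage].to_numpy()[:, None] * lib[None, :]
        lam = rng.gamma(shape, m / shape)
        counts = rng.poisson(lam).astype(np.int32)
        blocks.append(counts)
        cell_types.extend([stage] * n_cells)

    X = np.concatenate(blocks, axis=1)  # genes x cells
    n_cells_total = X.shape[1]
    # simulated testis counts are dense (most genes fire in most stages), so a
    # dense matrix is both smaller and faster than CSR here
    X = np.ascontiguousarray(X.T)
    obs = pd.DataFrame(
        {
            "cell_type": pd.Categorical(cell_types, categories=list(config.stages)),
            "replicate": [f"rep{1 + i % 2}" for i in range(n_cells_total)],
        },
        index=[f"cell{i:05d}" for i in range(n_cells_total)],
    )
    adata = AnnData(
        X=X, obs=obs, var=annotation.copy(),
        uns={"regime": regime, "seed": config.seed},
    )
    return adata, truth


def _gametolog_map(annotation: pd.DataFrame) -> pd.DataFrame:
    neoy = annotation[annotation.chromosome == "neoY"]
    paired = neoy.dropna(subset=["gametolog_of"])
    return pd.DataFrame(
        {"neoX_id": paired.gametolog_of.to_numpy(), "neoY_id": paired.index.to_numpy()}
    )


# ---------------------------------------------------------------------------
# bulk two-species tables
# ---------------------------------------------------------------------------

@dataclass
class BulkPair:
    """Matched bulk expression tables for ingroup and outgroup species.

    ``outgroup`` / ``ingroup`` carry multiplicative lognormal measurement
    noise; ``expected_*`` are the noise-free ground truth. ``pairs`` maps
    outgroup genes to their ingroup orthologs (identity mapping; the neo-Y is
    ingroup-specific and is reachable through the annotation's gametolog map).
    """

    outgroup: pd.DataFrame
    ingroup: pd.DataFrame
    expected_outgroup: pd.DataFrame
    expected_ingroup: pd.DataFrame
    pairs: pd.DataFrame
    tissues: tuple


def simulate_bulk_pair(
    config: SimConfig,
    annotation: pd.DataFrame,
    tissues: list[str],
    pre_zga_tissues: tuple = ("embryo_preZGA",),
) -> tuple[BulkPair, GroundTruth]:
    """Simulate matched bulk expression for the two species across tissues.

    The outgroup (where the neo-X element is still autosomal) expresses every
    gene at its diploid baseline B_g. The ingroup expresses the neo-X at
    ``B * 0.5 * D`` (single copy, tissue-dependent compensation) and the neo-Y
    at ``B * 0.5 * gamma``. In pre-ZGA embryo tissues both species carry the
    identical maternally deposited pool (B_g; zero for the male-limited neo-Y),
    and in female tissues (name containing "ovary" or "female") the neo-Y is
    absent.
    """
    if not tissues:
        raise ValueError("tissue list must be nonempty")
    if not any(t in pre_zga_tissues for t in tissues):
        raise ValueError("tissues must include a pre-ZGA embryo stage")
    if "testis" not in tissues:
        raise ValueError("tissues must include a testis sample")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    chrom = annotation.chromosome
    base = annotation.baseline.to_numpy(float)
    gamma = annotation.y_retention.to_numpy(float)
    boost = chrom.map(lambda c: config.dc_boost_max.get(c, 1.0)).to_numpy(float)
    dist = annotation.msl_distance.to_numpy(float)
    decay = np.where(np.isfinite(dist), np.exp(-dist / config.dc_distance_scale), 0.0)
    is_neox = (chrom == "MullerC").to_numpy()
    is_neoy = (chrom == "neoY").to_numpy()

    out_genes = annotation.index[~is_neoy]
    exp_out = pd.DataFrame(index=out_genes, columns=tissues, dtype=float)
    exp_in = pd.DataFrame(index=annotation.index, columns=tissues, dtype=float)

    for tissue in tissues:
        if tissue in pre_zga_tissues:
            exp_out[tissue] = base[~is_neoy]
            e = base.copy()
            e[is_neoy] = 0.0
            exp_in[tissue] = e
            continue
        exp_out[tissue] = base[~is_neoy]
        profile = config.dc_tissue_profile.get(tissue, 1.0)
        d = np.minimum(1.0 + (boost - 1.0) * profile * decay, boost)
        e = base.copy()
        e[is_neox] = base[is_neox] * 0.5 * d[is_neox]
        e[is_neoy] = base[is_neoy] * 0.5 * gamma[is_neoy]
        if "ovary" in tissue or "female" in tissue:
            e[is_neoy] = 0.0
        exp_in[tissue] = e

    def noisy(expected: pd.DataFrame) -> pd.DataFrame:
        noise = np.exp(rng.normal(0.0, config.bulk_noise_logsd, expected.shape))
        return expected * noise

    pairs = pd.DataFrame({
        "outgroup_id": out_genes,
        "ingroup_id": out_genes,
        "outgroup_chrom": chrom.loc[out_genes].to_numpy(),
        "ingroup_chrom": chrom.loc[out_genes].to_numpy(),
    })
    bulk = BulkPair(
        outgroup=noisy(exp_out),
        ingroup=noisy(exp_in),
        expected_outgroup=exp_out,
        expected_ingroup=exp_in,
        pairs=pairs,
        tissues=tuple(tissues),
    )
    mu = _expected_mu(config, annotation, "NONE")
    truth = GroundTruth(
        mu=mu, xa=_true_xa(mu, annotation),
        gametolog_map=_gametolog_map(annotation),
        msl_distance=annotation.msl_distance.copy(),
    )
    return bulk, truth


# ---------------------------------------------------------------------------
# CDS trios
# ---------------------------------------------------------------------------

@dataclass
class CdsTrios:
    """Simulated coding sequences for gametolog-calling exercises.

    ``outgroup`` holds the ancestral CDS set; ``ingroup_noX`` the ingroup CDS
    set with neo-X genes masked out (so only neo-Y descendants remain) and
    ``ingroup_noY`` vice versa. ``truth`` records the true pairings, losses and
    truncation fractions.
    """

    outgroup: dict
    ingroup_noX: dict
    ingroup_noY: dict
    truth: pd.DataFrame

    @property
    def neoX_ids(self) -> list:
        return sorted(self.ingroup_noY)

    @property
    def neoY_ids(self) -> list:
        return sorted(self.ingroup_noX)


def _mutate(seq: np.ndarray, rate: float, rng) -> np.ndarray:
    if rate <= 0:
        return seq.copy()
    hits = rng.random(len(seq)) < rate
    out = seq.copy()
    if hits.any():
        # substitute with one of the three other bases
        shift = rng.integers(1, 4, size=int(hits.sum()))
        idx = np.searchsorted(_BASES, out[hits])
        out[hits] = _BASES[(idx + shift) % 4]
    return out


def simulate_cds_trios(config: SimConfig) -> CdsTrios:
    """Generate ancestral CDS plus diverged neo-X/neo-Y descendants.

    Each ancestor spawns a neo-X copy (unless lost) and a neo-Y copy (unless
    lost) carrying independent point substitutions at ``trio_mutation_rate``
    per site; a fraction of neo-Y copies are 3'-truncated. Status in the truth
    table is one of {both, X_only, Y_only, none}.
    """
    if not (0.0 <= config.trio_mutation_rate <= 0.25):
        raise SimConfigError("trio_mutation_rate must be in [0, 0.25]")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    lo, hi = config.trio_cds_len_range

    outgroup, no_x, no_y = {}, {}, {}
    rows = []
    for i in range(config.n_trios):
        anc_id, x_id, y_id = f"anc_g{i:04d}", f"neoX_g{i:04d}", f"neoY_g{i:04d}"
        length = int(rng.integers(lo, hi + 1))
        anc = _BASES[rng.integers(0, 4, size=length)]
        outgroup[anc_id] = "".join(anc)

        keep_x = rng.random() >= config.x_loss_prob
        keep_y = rng.random() >= config.y_loss_prob
        trunc_frac = 0.0
        if keep_x:
            no_y[x_id] = "".join(_mutate(anc, config.trio_mutation_rate, rng))
        if keep_y:
            y_seq = _mutate(anc, config.trio_mutation_rate, rng)
            if rng.random() < config.y_truncation_prob:
                trunc_frac = float(rng.uniform(*config.y_truncation_range))
                y_seq = y_seq[: max(30, int(len(y_seq) * (1.0 - trunc_frac)))]
            no_x[y_id] = "".join(y_seq)

        status = {(True, True): "both", (True, False): "X_only",
                  (False, True): "Y_only", (False, False): "none"}[(keep_x, keep_y)]
        rows.append((
            anc_id,
            x_id if keep_x else None,
            y_id if keep_y else None,
            status,
            len(no_y[x_id]) if keep_x else np.nan,
            len(no_x[y_id]) if keep_y else np.nan,
            trunc_frac,
        ))

    truth = pd.DataFrame(rows, columns=[
        "outgroup_id", "neoX_id", "neoY_id", "status",
        "neoX_cds_len", "neoY_cds_len", "trunc_fraction",
    ]).set_index("outgroup_id")
    if truth.status.eq("none").all():
        warnings.warn("all trios lost both descendants", stacklevel=2)
    return CdsTrios(outgroup=outgroup, ingroup_noX=no_x, ingroup_noY=no_y, truth=truth)
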