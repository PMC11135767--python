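"""Gametolog identification and neo-Y dosage analyses.

Neo-X and neo-Y descendants of a single ancestral autosomal gene
("gametologs") are found by masked reciprocal best hits: the ingroup CDS set
is split into a copy without neo-X genes and a copy without neo-Y genes, and
each outgroup gene's best mutual local-alignment partner in each masked set
is taken when it lies on the expected chromosome. Downstream analyses ask
whether neo-Y transcription rescues the dosage deficit of the incompletely
compensated neo-X (combined X+Y expression), whether neo-Y copies are
truncated, whether they remain translated (ribosome occupancy), and which
genes have become Y-biased.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align
from scipy import stats


@dataclass(frozen=True)
class ScoringScheme:
    """Nucleotide local-alignment scoring (affine gaps; the first gap base
    costs ``gap_open``, each further base ``gap_extend``)."""

    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -5.0
    gap_extend: float = -2.0


DEFAULT_SCORING = ScoringScheme()


@dataclass
class AlignmentHit:
    query_id: str
    subject_id: str
    score: float
    align_length: int
    identity: float
    scoring: ScoringScheme = DEFAULT_SCORING


def _aligner(scoring: ScoringScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def _alignment_stats(alignment) -> tuple[int, float]:
    """(number of alignment columns, identity fraction) of one alignment."""
    counts = alignment.counts()
    length = counts.identities + counts.mismatches + counts.gaps
    identity = counts.identities / length if length else 0.0
    return int(length), float(identity)


def local_align(
    seq_a: str,
    seq_b: str,
    scoring: ScoringScheme = DEFAULT_SCORING,
    query_id: str = "query",
    subject_id: str = "subject",
) -> AlignmentHit:
    """Smith-Waterman local alignment of two nucleotide sequences.

    Symmetric in its arguments: score(A, B) == score(B, A).
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    aligner = _aligner(scoring)
    alignments = aligner.align(seq_a.upper(), seq_b.upper())
    if alignments.score <= 0:
        # no positive-scoring local alignment exists
        return AlignmentHit(query_id, subject_id, 0.0, 0, 0.0, scoring)
    best = alignments[0]
    length, identity = _alignment_stats(best)
    return AlignmentHit(query_id, subject_id, float(best.score), length, identity,
                        scoring)


def align_score(seq_a: str, seq_b: str,
                scoring: ScoringScheme = DEFAULT_SCORING) -> float:
    """Local alignment score only (no traceback; used for all-vs-all scans)."""
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    return float(_aligner(scoring).score(seq_a.upper(), seq_b.upper()))


def select_longest_cds(records: dict) -> dict:
    """Pick one CDS per gene: the longest, ties broken by smallest record id.

    ``records`` maps gene id -> {record_id: sequence}; returns
    gene id -> (record_id, sequence).
    """
    out = {}
    for gene, recs in records.items():
        if not recs:
            raise ValueError(f"no CDS records for gene {gene!r}")
        best = min(recs, key=lambda rid: (-len(recs[rid]), rid))
        out[gene] = (best, recs[best])
    return out


def _best_hits(score: np.ndarray, rows: list, cols: list,
               seqs_a: dict, seqs_b: dict,
               scoring: ScoringScheme) -> dict:
    """Best column per row: max score, ties by longest alignment then id."""
    best = {}
    for i, rid in enumerate(rows):
        s = score[i]
        top = s.max()
        tied = [cols[j] for j in np.flatnonzero(s == top)]
        if len(tied) > 1:
            lengths = {
                cid: local_align(seqs_a[rid], seqs_b[cid], scoring).align_length
                for cid in tied
            }
            longest = max(lengths.values())
            tied = sorted(cid for cid in tied if lengths[cid] == longest)
        best[rid] = tied[0]
    return best


def reciprocal_best_hits(
    set_a: dict,
    set_b: dict,
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> list:
    """Mutual best local-alignment partners between two CDS sets.

    Returns (a_id, b_id) pairs sorted by a_id. A pair survives only if each
    member is the other's best hit (highest score; ties broken by longest
    aligned length, then smallest subject id).
    """
    if not set_a or not set_b:
        return []
    a_ids, b_ids = sorted(set_a), sorted(set_b)
    aligner = _aligner(scoring)
    score = np.empty((len(a_ids), len(b_ids)))
    for i, aid in enumerate(a_ids):
        sa = set_a[aid].upper()
        for j, bid in enumerate(b_ids):
            score[i, j] = aligner.score(sa, set_b[bid].upper())

    best_ab = _best_hits(score, a_ids, b_ids, set_a, set_b, scoring)
    best_ba = _best_hits(score.T, b_ids, a_ids, set_b, set_a, scoring)
    return sorted(
        (aid, bid) for aid, bid in best_ab.items() if best_ba[bid] == aid
    )


def classify_truncation(neox_cds_len: float, neoy_cds_len: float) -> bool:
    """Neo-Y CDS counted as truncated iff shorter than 80% of the neo-X CDS
    (strict inequality)."""
    if not np.isfinite(neox_cds_len) or not np.isfinite(neoy_cds_len):
        raise ValueError("both CDS lengths must be known")
    return bool(neoy_cds_len < 0.8 * neox_cds_len)


def call_gametologs(
    outgroup: dict,
    ingroup_no_x: dict,
    ingroup_no_y: dict,
    neox_ids,
    neoy_ids,
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> pd.DataFrame:
    """Assemble gametolog trios from masked reciprocal best hits.

    The neo-Y gametolog of an outgroup gene is its RBH partner in the
    neo-X-masked set when that partner is neo-Y-linked; the neo-X gametolog
    comes from the neo-Y-masked set symmetrically. Partners on other
    chromosomes (moved genes) are not recorded as gametologs. Returns a frame
    indexed by outgroup id with neoX_id, neoY_id, status (both / X_only /
    Y_only), CDS lengths, and the truncation flag (defined only for status
    'both').
    """
    neox_ids, neoy_ids = set(neox_ids), set(neoy_ids)
    clash = neox_ids & neoy_ids
    if clash:
        raise ValueError(f"ids present in both masks: {sorted(clash)[:3]}")

    rbh_y = dict(reciprocal_best_hits(outgroup, ingroup_no_x, scoring))
    rbh_x = dict(reciprocal_best_hits(outgroup, ingroup_no_y, scoring))

    rows = []
    for anc in sorted(outgroup):
        x_hit = rbh_x.get(anc)
        y_hit = rbh_y.get(anc)
        x_id = x_hit if x_hit in neox_ids else None
        y_id = y_hit if y_hit in neoy_ids else None
        if x_id is None and y_id is None:
            continue
        status = "both" if (x_id and y_id) else ("X_only" if x_id else "Y_only")
        lx = float(len(ingroup_no_y[x_id])) if x_id else np.nan
        ly = float(len(ingroup_no_x[y_id])) if y_id else np.nan
        trunc = classify_truncation(lx, ly) if status == "both" else np.nan
        rows.append((anc, x_id, y_id, status, lx, ly, trunc))
    return pd.DataFrame(rows, columns=[
        "outgroup_id", "neoX_id", "neoY_id", "status",
        "neoX_cds_len", "neoY_cds_len", "truncated_Y",
    ]).set_index("outgroup_id")


# ---------------------------------------------------------------------------
# expression analyses over trios
# ---------------------------------------------------------------------------

def y_biased_genes(
    expr_x,
    expr_y,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Flag trios whose neo-Y gametolog out-expresses the neo-X copy.

    Per trio, a one-sided exact binomial test of the pooled neo-Y count
    against half of the X+Y total; Benjamini-Hochberg across tested trios.
    Flagged iff q <= alpha and Y > X. Trios with X+Y = 0 are untested.
    """
    x = pd.Series(expr_x).round().astype(int)
    y = pd.Series(expr_y).round().astype(int)
    if (x < 0).any() or (y < 0).any():
        raise ValueError("counts must be nonnegative")
    total = x + y
    p = pd.Series(np.nan, index=x.index)
    tested = total > 0
    p.loc[tested] = [
        stats.binomtest(int(k), int(n), 0.5, alternative="greater").pvalue
        for k, n in zip(y[tested], total[tested])
    ]
    q = pd.Series(np.nan, index=x.index)
    if tested.any():
        q.loc[tested] = stats.false_discovery_control(p[tested], method="bh")
    flag = tested & (q <= alpha) & (y > x)
    return pd.DataFrame({
        "x_count": x, "y_count": y, "p": p, "q": q,
        "y_biased": flag.fillna(False).astype(bool),
        "tested": tested,
    })


def _eps_for(num: np.ndarray, den: np.ndarray, eps: float) -> np.ndarray:
    """0 pseudocount where both sides are positive, else ``eps``."""
    both_pos = (num > 0) & (den > 0)
    return np.where(both_pos, 0.0, eps)


def combined_dosage(
    expr_neox: pd.DataFrame,
    expr_neoy: pd.DataFrame,
    expr_outgroup: pd.DataFrame,
    eps: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Combined X+Y dosage of gametolog trios relative to the outgroup.

    Inputs are trio-aligned genes x tissues tables in a common normalized
    unit. Returns per-gene log2 fold-differences (``log2_combined`` for
    (X + Y) / outgroup and ``log2_neox`` for X / outgroup, long format) and
    per-tissue medians of both. Trios with any member missing are skipped
    with a warning.
    """
    common = expr_neox.index.intersection(expr_neoy.index).intersection(
        expr_outgroup.index)
    skipped = len(expr_outgroup.index.union(expr_neox.index)
                  .union(expr_neoy.index)) - len(common)
    if skipped:
        warnings.warn(f"skipped {skipped} trios with missing members", stacklevel=2)

    rows = []
    for tissue in expr_outgroup.columns:
        x = expr_neox.loc[common, tissue].to_numpy(float)
        y = expr_neoy.loc[common, tissue].to_numpy(float)
        out = expr_outgroup.loc[common, tissue].to_numpy(float)
        e_comb = _eps_for(x + y, out, eps)
        e_x = _eps_for(x, out, eps)
        rows.append(pd.DataFrame({
            "gene": common, "tissue": tissue,
            "log2_combined": np.log2((x + y + e_comb) / (out + e_comb)),
            "log2_neox": np.log2((x + e_x) / (out + e_x)),
        }))
    folds = pd.concat(rows, ignore_index=True)
    medians = folds.groupby("tissue")[["log2_combined", "log2_neox"]].median()
    return folds, medians


def ribosome_occupancy(
    ribo_tpm: pd.Series,
    rna_tpm: pd.Series,
    chromosome: pd.Series,
    truncated: pd.Series | None = None,
    eps: float = 0.01,
) -> tuple[pd.Series, pd.DataFrame]:
    """Translation proxy: ribosome-profiling TPM over RNA TPM per gene.

    Returns the per-gene occupancy and a summary frame with per-chromosome
    medians, a Wilcoxon rank-sum p of neo-Y vs the autosomal reference arms,
    and (if ``truncated`` flags are given) the truncated-vs-untruncated neo-Y
    comparison.
    """
    common = ribo_tpm.index.intersection(rna_tpm.index)
    r = ribo_tpm.loc[common].to_numpy(float)
    m = rna_tpm.loc[common].to_numpy(float)
    e = _eps_for(r, m, eps)
    occ = pd.Series((r + e) / (m + e), index=common, name="occupancy")
    chrom = chromosome.loc[common]

    rows = [(c, float(occ[chrom == c].median()), int((chrom == c).sum()))
            for c in pd.unique(chrom)]
    summary = pd.DataFrame(rows, columns=["group", "median", "n"])

    auto = occ[chrom.isin(("MullerB", "MullerE"))]
    neoy = occ[chrom == "neoY"]
    p_neoy = (stats.mannwhitneyu(neoy, auto, alternative="two-sided").pvalue
              if len(neoy) >= 3 and len(auto) >= 3 else np.nan)
    extra = [("neoY_vs_autosomes_p", p_neoy, len(neoy))]

    if truncated is not None:
        trunc = truncated.reindex(common)
        t = occ[(chrom == "neoY") & (trunc == True)]  # noqa: E712
        u = occ[(chrom == "neoY") & (trunc == False)]  # noqa: E712
        extra.append(("neoY_truncated_median", float(t.median()) if len(t) else np.nan,
                      len(t)))
        extra.append(("neoY_untruncated_median",
                      float(u.median()) if len(u) else np.nan, len(u)))
        p_tr = (stats.mannwhitneyu(t, u, alternative="two-sided").pvalue
                if len(t) >= 3 and len(u) >= 3 else np.nan)
        extra.append(("truncated_vs_untruncated_p", p_tr, len(t) + len(u)))
    summary = pd.concat(
        [summary, pd.DataFrame(extra, columns=["group", "median", "n"])],
        ignore_index=True)
    return occ, summary
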