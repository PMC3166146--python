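"""cis-eQTL calling in one tissue for one sample subset.

Pipeline per scan: (1) drop SNPs whose minor allele frequency, recomputed on
the subset, does not strictly exceed the threshold; (2) for every transcript
test each retained SNP inside the cis window (TSS +/- 1 Mb) with the
tie-corrected Kruskal-Wallis rank test over the genotype classes {0,1,2};
(3) keep only the smallest-p SNP per transcript (the lead eSNP); (4) set the
reporting threshold so the permutation-estimated FDR stays at or below the
target (default 10%), where each permutation shuffles the expression sample
labels and repeats the full scan including lead selection.

An "eQTL" is identified with its transcript (at most one lead association
per transcript per tissue); the "eSNP" is the selected lead SNP.

The scan's Kruskal-Wallis statistic is computed with a vectorized rank-sum
formulation so that all window SNPs and all permutation columns of one
transcript are handled in a few matrix products; the scalar
:func:`kruskal_wallis` exposes the same statistic for a single pair.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import Cohort, MISSING

CIS_WINDOW_BP = 1_000_000
MAF_THRESHOLD = 0.05
FDR_TARGET = 0.10
N_PERMUTATIONS = 10

_P_FLOOR = 1e-300  # keep p in (0, 1] despite chi-square underflow


@dataclass(frozen=True)
class CisEqtl:
    """One transcript's lead cis association in one tissue."""

    transcript_id: str
    tissue: str
    lead_snp_id: str
    p_value: float
    h_statistic: float
    distance_bp: int  # signed: snp_pos - tss
    n_used: int
    significant: bool

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside (0, 1]")


@dataclass
class ScanResult:
    """All lead associations of one scan plus the FDR decision rule.

    ``leads`` holds one entry per transcript that had any testable window
    SNP; the significant subset is the cis-eQTL set Q and their lead SNPs
    the eSNP set S.
    """

    tissue: str
    leads: list[CisEqtl]
    p_threshold: float
    fdr_target: float
    n_permutations: int
    n_samples: int

    @property
    def eqtls(self) -> list[CisEqtl]:
        return [e for e in self.leads if e.significant]

    @property
    def eqtl_transcripts(self) -> set[str]:
        return {e.transcript_id for e in self.eqtls}

    @property
    def esnp_ids(self) -> set[str]:
        return {e.lead_snp_id for e in self.eqtls}

    @property
    def q(self) -> int:
        return len(self.eqtls)

    @property
    def s(self) -> int:
        return len(self.esnp_ids)

    def lead_for(self, transcript_id: str) -> CisEqtl | None:
        for e in self.leads:
            if e.transcript_id == transcript_id:
                return e
        return None


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

def compute_maf(column: np.ndarray) -> float:
    """Minor allele frequency of one dosage column (missing excluded)."""
    column = np.asarray(column)
    observed = column[column != MISSING]
    if observed.size == 0:
        raise ValueError("cannot compute MAF: all genotypes missing")
    freq = observed.sum() / (2.0 * observed.size)
    return float(min(freq, 1.0 - freq))


def filter_snps_by_maf(values: np.ndarray, threshold: float = MAF_THRESHOLD,
                       ) -> np.ndarray:
    """Boolean mask of SNP columns whose MAF strictly exceeds ``threshold``.

    ``values`` is a samples x SNPs dosage matrix restricted to the subset of
    interest: the filter is recomputed on each subsample, so a SNP common in
    the full cohort can fail in a small nested subset.  All-missing columns
    are dropped.
    """
    values = np.asarray(values)
    present = values != MISSING
    n_obs = present.sum(axis=0)
    with np.errstate(invalid="ignore"):
        alt = np.where(present, values, 0).sum(axis=0) / np.maximum(2 * n_obs, 1)
    maf = np.minimum(alt, 1.0 - alt)
    return (n_obs > 0) & (maf > threshold)


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------

def _tie_correction(ranks: np.ndarray) -> float:
    """1 - sum(t^3 - t) / (N^3 - N) over tied groups; 0 if all values tie."""
    n = ranks.size
    if n < 2:
        return 0.0
    _, counts = np.unique(ranks, return_counts=True)
    return 1.0 - (counts ** 3 - counts).sum() / float(n ** 3 - n)


def kruskal_wallis(values: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and chi-square p for one SNP.

    ``groups`` are genotype classes; negative entries (missing) are dropped
    pairwise together with their expression values.  Degenerate signals —
    fewer than two non-empty genotype classes, or a constant expression
    vector — are not testable and return (0.0, 1.0), i.e. no association.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    keep = groups != MISSING
    values, groups = values[keep], groups[keep]
    labels = np.unique(groups)
    if labels.size < 2 or values.size < 3:
        return 0.0, 1.0
    ranks = stats.rankdata(values)
    correction = _tie_correction(ranks)
    if correction == 0.0:
        return 0.0, 1.0
    n = values.size
    h = 0.0
    for label in labels:
        in_group = groups == label
        h += ranks[in_group].sum() ** 2 / in_group.sum()
    h = (12.0 / (n * (n + 1.0)) * h - 3.0 * (n + 1.0)) / correction
    h = max(h, 0.0)
    p = float(stats.chi2.sf(h, df=labels.size - 1))
    return float(h), max(p, _P_FLOOR)


def _kw_batch(rank_columns: np.ndarray, onehot: np.ndarray,
              counts: np.ndarray, correction: float,
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """H and p for every (window SNP, rank column) pair at once.

    Parameters
    ----------
    rank_columns : (n, P) float
        One column of expression ranks per permutation (column 0 observed).
    onehot : (3, n, m) bool
        Genotype-class indicators for the m window SNPs (complete data).
    counts : (3, m) int
        Per-SNP genotype class sizes.
    correction : float
        Pooled tie correction of the rank vector (shared by all columns,
        since permuting labels permutes ranks).

    Returns (h, p, testable) with shapes (m, P), (m, P), (m,).
    """
    n = rank_columns.shape[0]
    nonempty = counts > 0
    testable = nonempty.sum(axis=0) >= 2
    m, p_cols = onehot.shape[2], rank_columns.shape[1]
    h = np.zeros((m, p_cols))
    if correction > 0.0:
        for g in range(onehot.shape[0]):
            if not nonempty[g].any():
                continue
            sums = onehot[g].reshape(n, m).T.astype(float) @ rank_columns
            with np.errstate(divide="ignore", invalid="ignore"):
                term = sums ** 2 / counts[g][:, None]
            h += np.where(nonempty[g][:, None], term, 0.0)
        h = (12.0 / (n * (n + 1.0)) * h - 3.0 * (n + 1.0)) / correction
        np.clip(h, 0.0, None, out=h)
    df = np.maximum(nonempty.sum(axis=0) - 1, 1)
    p = stats.chi2.sf(h, df=df[:, None])
    p = np.where(testable[:, None] & (correction > 0.0), p, 1.0)
    h = np.where(testable[:, None] & (correction > 0.0), h, 0.0)
    return h, np.maximum(p, _P_FLOOR), testable


# ---------------------------------------------------------------------------
# lead-SNP selection
# ---------------------------------------------------------------------------

def _pick_lead(p_values: np.ndarray, abs_distance: np.ndarray,
               id_rank: np.ndarray) -> int:
    """Index of the smallest-p SNP; ties by |distance| then lexicographic id."""
    order = np.lexsort((id_rank, abs_distance, p_values))
    return int(order[0])


def scan_transcript(expression: np.ndarray, genotype_window: np.ndarray,
                    snp_ids: np.ndarray, snp_pos: np.ndarray, tss: int,
                    ) -> tuple[str, float, float, int] | None:
    """Best association of one transcript over the SNPs of its cis window.

    ``genotype_window`` must already be restricted to the sample subset and
    MAF-filtered window SNPs.  Returns (snp_id, H, p, signed distance) for
    the lead SNP, or None when the window is empty.  Every window SNP is
    tested; non-testable SNPs count as p = 1 and can still be the lead when
    nothing better exists.
    """
    snp_ids = np.asarray(snp_ids, dtype=object)
    snp_pos = np.asarray(snp_pos, dtype=np.int64)
    genotype_window = np.atleast_2d(np.asarray(genotype_window))
    if genotype_window.shape[1] == 0:
        return None
    results = [kruskal_wallis(expression, genotype_window[:, j])
               for j in range(genotype_window.shape[1])]
    h = np.array([r[0] for r in results])
    p = np.array([r[1] for r in results])
    distance = snp_pos - int(tss)
    id_rank = np.argsort(np.argsort(snp_ids.astype(str)))
    best = _pick_lead(p, np.abs(distance), id_rank)
    return (str(snp_ids[best]), float(h[best]), float(p[best]),
            int(distance[best]))


# ---------------------------------------------------------------------------
# permutation FDR
# ---------------------------------------------------------------------------

def permutation_fdr(observed_p: np.ndarray,
                    permuted_p: list[np.ndarray],
                    fdr_target: float = FDR_TARGET) -> float:
    """Reporting threshold from pooled permutation lead p-values.

    FDR(p*) = mean over permutations of #{permuted lead p <= p*} divided by
    #{observed lead p <= p*}, evaluated at every observed p and made
    monotone non-decreasing in p by the q-value-style running minimum from
    the largest observed p downward.  Returns the largest observed p whose
    monotone FDR is <= ``fdr_target``; 0.0 when no observed p qualifies
    (empty result).  Note the threshold equals the largest observed p whose
    *raw* FDR estimate qualifies, so a noisy high estimate at a smaller p
    cannot veto a well-supported larger threshold.
    """
    observed_p = np.sort(np.asarray(observed_p, dtype=float))
    if observed_p.size == 0:
        raise ValueError("permutation FDR needs at least one observed test")
    if len(permuted_p) == 0:
        raise ValueError("permutation FDR needs at least one permutation")
    pooled = np.sort(np.concatenate([np.asarray(p, dtype=float)
                                     for p in permuted_p]))
    n_perm = len(permuted_p)
    # counts at each candidate threshold (the observed p-values themselves)
    perm_hits = np.searchsorted(pooled, observed_p, side="right") / n_perm
    obs_hits = np.searchsorted(observed_p, observed_p, side="right")
    fdr = perm_hits / obs_hits
    fdr = np.minimum.accumulate(fdr[::-1])[::-1]
    ok = fdr <= fdr_target
    if not ok.any():
        return 0.0
    return float(observed_p[np.nonzero(ok)[0][-1]])


# ---------------------------------------------------------------------------
# full scan
# ---------------------------------------------------------------------------

def call_cis_eqtls(cohort: Cohort, tissue: str,
                   subset: np.ndarray | list | None = None, *,
                   fdr_target: float = FDR_TARGET,
                   n_permutations: int = N_PERMUTATIONS,
                   seed: int = 0,
                   window_bp: int = CIS_WINDOW_BP,
                   maf_threshold: float = MAF_THRESHOLD) -> ScanResult:
    """Call cis eQTLs for one tissue on one sample subset.

    ``subset`` is a collection of sample ids (or None for the full cohort).
    Deterministic given ``seed``, which drives the expression-label
    permutations of the FDR estimate.
    """
    if tissue not in cohort.expression:
        raise KeyError(f"tissue {tissue!r} not in cohort {cohort.tissues}")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    sample_index = {s: i for i, s in enumerate(cohort.sample_ids)}
    if subset is None:
        idx = np.arange(cohort.n_samples)
    else:
        missing = [s for s in subset if s not in sample_index]
        if missing:
            raise KeyError(f"subset samples not in cohort: {missing[:5]}")
        idx = np.array([sample_index[s] for s in subset])
    n = idx.size
    if n < 3:
        raise ValueError("subset must contain at least 3 samples")

    geno = cohort.genotypes.values[idx]
    keep = filter_snps_by_maf(geno, maf_threshold)
    geno = geno[:, keep]
    pos = cohort.snps.pos[keep]
    snp_ids = cohort.snps.ids[keep]
    expr = cohort.expression[tissue].values[:, idx]
    transcripts = cohort.transcripts

    rng = np.random.default_rng(seed)
    perms = np.vstack([np.arange(n)] +
                      [rng.permutation(n) for _ in range(n_permutations)])

    has_missing_col = (geno == MISSING).any(axis=0)
    onehot_all = np.stack([geno == g for g in (0, 1, 2)])  # (3, n, m_kept)
    counts_all = onehot_all.sum(axis=1)

    lead_rows: list[tuple[str, str, float, float, int]] = []
    perm_leads: list[list[float]] = [[] for _ in range(n_permutations)]
    for i, transcript in enumerate(transcripts.ids):
        tss = int(transcripts.tss[i])
        lo = np.searchsorted(pos, tss - window_bp, side="left")
        hi = np.searchsorted(pos, tss + window_bp, side="right")
        if hi <= lo:
            continue
        window = slice(lo, hi)
        y = expr[i]
        ranks = stats.rankdata(y)
        correction = _tie_correction(ranks)
        rank_columns = ranks[perms].T  # (n, P+1)
        if has_missing_col[window].any():
            h, p = _scan_window_with_missing(y, geno[:, window], perms)
        else:
            h, p, _ = _kw_batch(rank_columns, onehot_all[:, :, window],
                                counts_all[:, window], correction)
        distance = pos[window] - tss
        ids_window = snp_ids[window].astype(str)
        id_rank = np.argsort(np.argsort(ids_window))
        best = _pick_lead(p[:, 0], np.abs(distance), id_rank)
        lead_rows.append((str(transcript), str(ids_window[best]),
                          float(h[best, 0]), float(p[best, 0]),
                          int(distance[best])))
        p_min = p.min(axis=0)
        for k in range(n_permutations):
            perm_leads[k].append(float(p_min[k + 1]))

    if not lead_rows:
        raise ValueError("no transcript had a testable cis window")
    observed_p = np.array([row[3] for row in lead_rows])
    threshold = permutation_fdr(observed_p,
                                [np.array(v) for v in perm_leads], fdr_target)
    leads = [CisEqtl(t, tissue, snp, p_val, h_val, dist, n,
                     significant=(threshold > 0.0 and p_val <= threshold))
             for (t, snp, h_val, p_val, dist) in lead_rows]
    return ScanResult(tissue, leads, threshold, fdr_target, n_permutations, n)


def _scan_window_with_missing(y: np.ndarray, window_geno: np.ndarray,
                              perms: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Slow path: per-SNP pairwise-complete KW for windows with missing calls."""
    m = window_geno.shape[1]
    n_cols = perms.shape[0]
    h = np.zeros((m, n_cols))
    p = np.ones((m, n_cols))
    for j in range(m):
        g = window_geno[:, j]
        for c in range(n_cols):
            h[j, c], p[j, c] = kruskal_wallis(y[perms[c]], g)
    return h, p


def write_scan_tsv(result: ScanResult, path: str | os.PathLike) -> None:
    """Persist one scan as TSV with the FDR threshold in a header comment."""
    with open(path, "w") as handle:
        handle.write(f"# tissue={result.tissue}\tp_threshold={result.p_threshold:.6g}"
                     f"\tfdr_target={result.fdr_target}"
                     f"\tn_permutations={result.n_permutations}"
                     f"\tn_samples={result.n_samples}\n")
        handle.write("transcript_id\ttissue\tlead_snp\tH\tp\tdistance_bp\tsignificant\n")
        for e in result.leads:
            handle.write(f"{e.transcript_id}\t{e.tissue}\t{e.lead_snp_id}"
                         f"\t{e.h_statistic:.6g}\t{e.p_value:.6g}"
                         f"\t{e.distance_bp}\t{int(e.significant)}\n")
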