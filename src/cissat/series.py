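"""Nested log-spaced subsample design and per-step, per-tissue scans.

The saturation design draws K sample sizes equally spaced in ln(n) between
n_min and the full cohort size, builds one nested chain of subsets
N_1 c N_2 c ... c N_K (so each step only removes individuals from the
next), and re-runs the complete cis-eQTL scan — including the per-subsample
MAF filter and permutation FDR — for every step and tissue.  The whole
procedure is repeated over independent replicate chains on the same cohort.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Cohort
from .scan import (FDR_TARGET, MAF_THRESHOLD, N_PERMUTATIONS, CIS_WINDOW_BP,
                   ScanResult, call_cis_eqtls, write_scan_tsv)

# fixed offsets that derive per-(replicate, step, tissue) sub-seeds from the
# master seed; one master seed reproduces every stage
_REPLICATE_STRIDE = 1_000_003
_STEP_STRIDE = 1_009
_SEED_MOD = 2 ** 31


def _sub_seed(master: int, replicate: int, step: int, tissue_index: int) -> int:
    return (master + _REPLICATE_STRIDE * replicate + _STEP_STRIDE * step
            + tissue_index) % _SEED_MOD


def log_spaced_sizes(n_min: int, n_max: int, k: int = 20) -> list[int]:
    """K sizes equally spaced in ln(n), endpoints exact.

    n_i = round(exp(ln n_min + (i-1) * (ln n_max - ln n_min) / (k-1))).
    Raises if rounding collapses two steps to the same size (choose a
    smaller k).
    """
    if n_min < 3:
        raise ValueError("n_min must be >= 3")
    if n_max <= n_min:
        raise ValueError("n_max must exceed n_min")
    if k < 2:
        raise ValueError("k must be >= 2")
    grid = np.exp(np.linspace(np.log(n_min), np.log(n_max), k))
    sizes = np.rint(grid).astype(int)
    sizes[0], sizes[-1] = n_min, n_max
    if len(set(sizes.tolist())) != k:
        raise ValueError(
            f"log-spaced sizes between {n_min} and {n_max} collide after "
            f"rounding at k={k}; choose a smaller k")
    return sizes.tolist()


@dataclass
class SubsampleSeries:
    """One nested chain N_1 c ... c N_K of sample-id subsets."""

    sizes: list[int]
    subsets: list[np.ndarray]  # sample ids, subsets[i] has sizes[i] entries
    replicate_id: int
    seed: int

    def __post_init__(self) -> None:
        if list(self.sizes) != sorted(set(self.sizes)):
            raise ValueError("sizes must be strictly increasing")
        for size, subset in zip(self.sizes, self.subsets):
            if len(subset) != size:
                raise ValueError("subset length disagrees with its size")
        for small, large in zip(self.subsets, self.subsets[1:]):
            if not set(small.tolist()) <= set(large.tolist()):
                raise ValueError("subsets are not nested")

    @property
    def k(self) -> int:
        return len(self.sizes)


def nested_subsamples(sample_ids: np.ndarray, sizes: list[int],
                      seed: int, replicate_id: int = 0) -> SubsampleSeries:
    """Build one nested chain from a single seeded permutation.

    Taking the first n_i elements of one random permutation is
    distributionally identical to repeatedly removing a uniform random set
    from the largest sample, and is deterministic given the seed.
    """
    sample_ids = np.asarray(sample_ids, dtype=object)
    if max(sizes) > sample_ids.size:
        raise ValueError(
            f"largest subsample {max(sizes)} exceeds cohort size {sample_ids.size}")
    if max(sizes) != sample_ids.size:
        raise ValueError(
            f"largest subsample {max(sizes)} must equal the cohort size "
            f"{sample_ids.size}")
    rng = np.random.default_rng(seed)
    permuted = sample_ids[rng.permutation(sample_ids.size)]
    subsets = [permuted[:n].copy() for n in sizes]
    return SubsampleSeries(list(sizes), subsets, replicate_id, seed)


@dataclass
class SeriesResult:
    """Scans of one replicate chain: (step, tissue) -> ScanResult."""

    replicate: int
    series: SubsampleSeries
    scans: dict[tuple[int, str], ScanResult]  # step is 1-based

    @property
    def steps(self) -> list[int]:
        return list(range(1, self.series.k + 1))

    @property
    def tissues(self) -> list[str]:
        return sorted({t for (_, t) in self.scans})

    def eqtl_sets(self, tissue: str) -> list[set[str]]:
        """Per-step significant transcript sets Q_1..Q_K for one tissue."""
        return [self.scans[(i, tissue)].eqtl_transcripts for i in self.steps]

    def esnp_sets(self, tissue: str) -> list[set[str]]:
        """Per-step lead-eSNP-id sets S_1..S_K for one tissue."""
        return [self.scans[(i, tissue)].esnp_ids for i in self.steps]

    def counts(self, tissue: str) -> list[int]:
        return [self.scans[(i, tissue)].q for i in self.steps]

    def manifest_frame(self) -> pd.DataFrame:
        rows = []
        for (step, tissue), scan in sorted(self.scans.items()):
            rows.append({"replicate": self.replicate, "step": step,
                         "n": self.series.sizes[step - 1], "tissue": tissue,
                         "q": scan.q, "s": scan.s,
                         "p_threshold": scan.p_threshold})
        return pd.DataFrame(rows)


def run_series(cohort: Cohort, *, n_min: int = 50, k: int = 20,
               fdr_target: float = FDR_TARGET,
               n_permutations: int = N_PERMUTATIONS,
               replicates: int = 5, seed: int = 0,
               window_bp: int = CIS_WINDOW_BP,
               maf_threshold: float = MAF_THRESHOLD,
               tissues: tuple[str, ...] | None = None,
               ) -> list[SeriesResult]:
    """Run the full nested design: all replicates, steps and tissues.

    Each replicate draws an independent nested chain (distinct sub-seed) on
    the same cohort; the MAF filter and permutation FDR are recomputed for
    every (step, tissue) scan.
    """
    sizes = log_spaced_sizes(n_min, cohort.n_samples, k)
    tissue_list = list(tissues) if tissues is not None else list(cohort.tissues)
    results = []
    for r in range(1, replicates + 1):
        series = nested_subsamples(cohort.sample_ids, sizes,
                                   seed=_sub_seed(seed, r, 0, 0), replicate_id=r)
        scans: dict[tuple[int, str], ScanResult] = {}
        for step, subset in enumerate(series.subsets, start=1):
            for t_index, tissue in enumerate(tissue_list):
                scans[(step, tissue)] = call_cis_eqtls(
                    cohort, tissue, subset,
                    fdr_target=fdr_target, n_permutations=n_permutations,
                    seed=_sub_seed(seed, r, step, t_index + 1),
                    window_bp=window_bp, maf_threshold=maf_threshold)
        results.append(SeriesResult(r, series, scans))
    return results


def write_series(results: list[SeriesResult], out_dir: str | os.PathLike,
                 ) -> str:
    """Persist scans as runs/rep{r}/step{i}/{tissue}.tsv plus a manifest TSV."""
    runs_dir = os.path.join(out_dir, "runs")
    for result in results:
        for (step, tissue), scan in result.scans.items():
            step_dir = os.path.join(runs_dir, f"rep{result.replicate}",
                                    f"step{step}")
            os.makedirs(step_dir, exist_ok=True)
            write_scan_tsv(scan, os.path.join(step_dir, f"{tissue}.tsv"))
    manifest = pd.concat([r.manifest_frame() for r in results],
                         ignore_index=True)
    manifest_path = os.path.join(out_dir, "manifest.tsv")
    manifest.to_csv(manifest_path, sep="\t", index=False)
    return manifest_path
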