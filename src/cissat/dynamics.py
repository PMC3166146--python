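"""Tissue-overlap classes of cis eQTLs and their dynamics across sample sizes.

At each subsample step every detected transcript falls in exactly one of
seven overlap classes — only_A, only_B, only_C (detected in a single
tissue), AB, BC, CA (detected in exactly one pair), ABC (detected in all
three).  Between consecutive steps a transcript can be created (newly
detected anywhere), deleted (no longer detected anywhere), or move between
classes; the four per-class rates (creation, deletion, move-in, move-out,
normalized by the change in sample size) summarize those transitions and
satisfy the exact bookkeeping identity

    count(i) = count(i-1) + creation + move_in - deletion - move_out.

The module also computes consecutive / reference overlap fractions for
eQTL (transcript) and eSNP (lead-SNP) sets, per-class distance and
association-strength summaries, and Mann-Whitney contrasts between
distance distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .series import SeriesResult

#: the seven overlap classes, single-tissue first
CLASSES = ("only_A", "only_B", "only_C", "AB", "BC", "CA", "ABC")

_MEMBER_TISSUES = {
    "only_A": ("A",), "only_B": ("B",), "only_C": ("C",),
    "AB": ("A", "B"), "BC": ("B", "C"), "CA": ("C", "A"),
    "ABC": ("A", "B", "C"),
}

RATE_KINDS = ("creation", "deletion", "move_in", "move_out")


def classify_overlap(q_a: set[str], q_b: set[str], q_c: set[str],
                     ) -> dict[str, str]:
    """Map each detected transcript to its overlap class."""
    labels: dict[str, str] = {}
    for transcript in q_a | q_b | q_c:
        key = (transcript in q_a, transcript in q_b, transcript in q_c)
        labels[transcript] = {
            (True, False, False): "only_A",
            (False, True, False): "only_B",
            (False, False, True): "only_C",
            (True, True, False): "AB",
            (False, True, True): "BC",
            (True, False, True): "CA",
            (True, True, True): "ABC",
        }[key]
    return labels


def class_counts(membership: dict[str, str]) -> dict[str, int]:
    counts = dict.fromkeys(CLASSES, 0)
    for label in membership.values():
        counts[label] += 1
    return counts


def consecutive_overlap_fraction(q_i: set[str], q_next: set[str]) -> float:
    """|Q_i & Q_{i+1}| / |Q_i| (denominator the earlier, smaller step).

    Returns NaN when Q_i is empty (undefined, reported as missing).
    """
    if not q_i:
        return float("nan")
    return len(q_i & q_next) / len(q_i)


def reference_overlap(q_i: set[str], q_ref: set[str]) -> tuple[float, float]:
    """(forward, backward) overlap of a subsample set with the reference set.

    forward = fraction of Q_i recovered in Q_ref; backward = fraction of
    Q_ref already present in Q_i.  Empty denominators give NaN.
    """
    inter = len(q_i & q_ref)
    forward = inter / len(q_i) if q_i else float("nan")
    backward = inter / len(q_ref) if q_ref else float("nan")
    return forward, backward


def transition_rates(previous: dict[str, str], current: dict[str, str],
                     delta_n: int) -> pd.DataFrame:
    """Per-class creation/deletion/move-in/move-out between two steps.

    ``previous`` and ``current`` map transcript -> class at consecutive
    steps of one replicate chain; transcripts absent from a map are
    undetected in every tissue at that step.  Returns one row per class
    with raw counts and counts per added individual.
    """
    if delta_n <= 0:
        raise ValueError("delta_n must be positive (consecutive growing steps)")
    counts = {label: dict.fromkeys(RATE_KINDS, 0) for label in CLASSES}
    for transcript, label in current.items():
        before = previous.get(transcript)
        if before is None:
            counts[label]["creation"] += 1
        elif before != label:
            counts[label]["move_in"] += 1
    for transcript, label in previous.items():
        after = current.get(transcript)
        if after is None:
            counts[label]["deletion"] += 1
        elif after != label:
            counts[label]["move_out"] += 1
    rows = []
    for label in CLASSES:
        row = {"class": label, "delta_n": delta_n}
        for kind in RATE_KINDS:
            row[kind] = counts[label][kind]
            row[f"{kind}_rate"] = counts[label][kind] / delta_n
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ClassTrajectory:
    """Per-step class membership and counts for one replicate chain."""

    replicate: int
    sizes: list[int]
    memberships: list[dict[str, str]]  # one map per step

    @property
    def k(self) -> int:
        return len(self.sizes)

    def counts_frame(self) -> pd.DataFrame:
        rows = []
        for step, membership in enumerate(self.memberships, start=1):
            counts = class_counts(membership)
            for label in CLASSES:
                rows.append({"replicate": self.replicate, "step": step,
                             "n": self.sizes[step - 1], "class": label,
                             "count": counts[label]})
        return pd.DataFrame(rows)

    def rates_frame(self) -> pd.DataFrame:
        frames = []
        for step in range(2, self.k + 1):
            delta = self.sizes[step - 1] - self.sizes[step - 2]
            frame = transition_rates(self.memberships[step - 2],
                                     self.memberships[step - 1], delta)
            frame.insert(0, "replicate", self.replicate)
            frame.insert(1, "step_pair", f"{step - 1}-{step}")
            frames.append(frame)
        return pd.concat(frames, ignore_index=True)


def build_trajectory(result: SeriesResult) -> ClassTrajectory:
    """Classify every step of one replicate chain into the 7 classes."""
    memberships = []
    for step in result.steps:
        memberships.append(classify_overlap(
            result.scans[(step, "A")].eqtl_transcripts,
            result.scans[(step, "B")].eqtl_transcripts,
            result.scans[(step, "C")].eqtl_transcripts))
    return ClassTrajectory(result.replicate, list(result.series.sizes),
                           memberships)


def overlap_frame(result: SeriesResult) -> pd.DataFrame:
    """Consecutive and reference overlap fractions for eQTL and eSNP sets.

    ``level`` is 'eqtl' (transcript identity) or 'esnp' (lead-SNP identity);
    ``kind`` is 'consecutive', 'forward_ref' or 'backward_ref', the
    reference being the largest subsample N_K.
    """
    rows = []
    for tissue in result.tissues:
        for level, sets in (("eqtl", result.eqtl_sets(tissue)),
                            ("esnp", result.esnp_sets(tissue))):
            reference = sets[-1]
            for step in range(1, len(sets)):
                rows.append({
                    "replicate": result.replicate, "tissue": tissue,
                    "level": level, "kind": "consecutive", "step": step,
                    "value": consecutive_overlap_fraction(sets[step - 1],
                                                          sets[step])})
            for step, current in enumerate(sets, start=1):
                forward, backward = reference_overlap(current, reference)
                rows.append({"replicate": result.replicate, "tissue": tissue,
                             "level": level, "kind": "forward_ref",
                             "step": step, "value": forward})
                rows.append({"replicate": result.replicate, "tissue": tissue,
                             "level": level, "kind": "backward_ref",
                             "step": step, "value": backward})
    return pd.DataFrame(rows)


def distance_strength_summary(membership: dict[str, str],
                              scans: dict[str, "object"],
                              ) -> pd.DataFrame:
    """Per class, per tissue mean |distance| (Mb) and mean -log10 p.

    ``scans`` maps tissue -> ScanResult for one step.  A class member
    contributes to the tissues of its class only (where it has a lead
    association); empty (class, tissue) cells are missing, not zero.
    """
    rows = []
    lead_tables = {}
    for tissue, scan in scans.items():
        lead_tables[tissue] = {e.transcript_id: e for e in scan.eqtls}
    for label in CLASSES:
        members = [t for t, c in membership.items() if c == label]
        for tissue in _MEMBER_TISSUES[label]:
            table = lead_tables.get(tissue, {})
            deltas = [abs(table[t].distance_bp) / 1e6
                      for t in members if t in table]
            strengths = [-np.log10(table[t].p_value)
                         for t in members if t in table]
            rows.append({
                "class": label, "tissue": tissue, "n_members": len(deltas),
                "mean_abs_delta_mb": float(np.mean(deltas)) if deltas else float("nan"),
                "mean_neglog10_p": float(np.mean(strengths)) if strengths else float("nan"),
            })
    return pd.DataFrame(rows)


def compare_distance_distributions(first, second) -> float:
    """Two-sided Mann-Whitney p between two distance samples.

    Exact null distribution for combined sizes <= 12 without ties, normal
    approximation with tie correction otherwise.  Rank-based, hence
    invariant under any monotone transform (e.g. log10) of the inputs.
    """
    first = np.asarray(first, dtype=float)
    second = np.asarray(second, dtype=float)
    if first.size == 0 or second.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([first, second])
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (combined.size <= 12 and not has_ties) else "asymptotic"
    return float(stats.mannwhitneyu(first, second, alternative="two-sided",
                                    method=method).pvalue)


def specificity_percentages(trajectory: ClassTrajectory, step: int,
                            ) -> pd.DataFrame:
    """Per tissue, % of its detections that are tissue-specific / shared by all.

    specific% = |only_T| / |detected in T|; shared_all% = |ABC| / |detected
    in T|.  Tissues with no detections at the step get missing values.
    """
    if not (1 <= step <= trajectory.k):
        raise ValueError(f"step {step} outside 1..{trajectory.k}")
    membership = trajectory.memberships[step - 1]
    counts = class_counts(membership)
    rows = []
    for tissue in ("A", "B", "C"):
        detected = sum(counts[label] for label in CLASSES
                       if tissue in _MEMBER_TISSUES[label])
        if detected == 0:
            specific = shared = float("nan")
        else:
            specific = 100.0 * counts[f"only_{tissue}"] / detected
            shared = 100.0 * counts["ABC"] / detected
        rows.append({"tissue": tissue, "step": step, "n_detected": detected,
                     "pct_specific": specific, "pct_shared_all": shared})
    return pd.DataFrame(rows)
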