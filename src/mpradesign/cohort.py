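"""Matched-background cohort construction.

MPRA candidates are drawn from common-variant pools, so raw genomic
background controls would differ systematically in allele frequency and in
proximity to transcription start/end sites.  Controls are therefore matched
to each positive jointly on (i) the AF percentile bin computed from the
positive set's own AF distribution and (ii) the TSS-proximity quintile,
at a 1:10 positives:controls ratio.  Groups (one positive plus its controls)
are the unit of the train/validation split so information never leaks across
the holdout boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, InfeasibleMatchError

REQUIRED_COLUMNS = ("CHROM", "POS", "REF", "ALT", "AF", "TSS_SCORE")


def af_percentile_bins(positive_afs, n_bins: int = 100) -> np.ndarray:
    """Empirical quantile boundaries of the positive AF distribution.

    Returns ``n_bins + 1`` ascending boundaries at equally spaced
    probabilities.  Bins are left-closed/right-open except the last, which is
    closed, so every positive falls in exactly one bin.
    """
    afs = np.asarray(list(positive_afs), dtype=float)
    if afs.size == 0:
        raise ConfigError("cannot compute percentile bins from an empty AF set")
    if n_bins < 1:
        raise ConfigError("n_bins must be >= 1")
    return np.quantile(afs, np.linspace(0.0, 1.0, n_bins + 1))


def assign_bin(values, boundaries: np.ndarray) -> np.ndarray:
    """Bin index per value; -1 for values outside [first, last] boundary."""
    values = np.asarray(values, dtype=float)
    n_bins = len(boundaries) - 1
    idx = np.searchsorted(boundaries, values, side="right") - 1
    idx = np.clip(idx, 0, n_bins - 1)
    idx[(values < boundaries[0]) | (values > boundaries[-1])] = -1
    return idx


@dataclass
class MatchedCohort:
    """Positives with their 1:``ratio`` matched controls.

    ``records`` holds one row per variant with GROUP (positive's variant id),
    ROLE ("positive"/"control"), RELAXED (group needed a nearest-cell
    fallback) and, after :func:`split_holdout`, SPLIT ("train"/"validation").
    """

    records: pd.DataFrame
    ratio: int = 10
    n_af_bins: int = 100
    relaxed_groups: list = field(default_factory=list)

    @property
    def groups(self) -> list:
        return list(self.records["GROUP"].unique())

    def positives(self) -> pd.DataFrame:
        return self.records[self.records["ROLE"] == "positive"]

    def controls(self) -> pd.DataFrame:
        return self.records[self.records["ROLE"] == "control"]

    def subset(self, split: str) -> pd.DataFrame:
        if "SPLIT" not in self.records.columns:
            raise ConfigError("cohort has no SPLIT column; call split_holdout first")
        return self.records[self.records["SPLIT"] == split]


def match_controls(
    positives: pd.DataFrame,
    pool: pd.DataFrame,
    ratio: int = 10,
    n_af_bins: int = 100,
    seed: int = 0,
) -> MatchedCohort:
    """Sample ``ratio`` background controls per positive, jointly matched.

    AF percentile bins (``n_af_bins``) and TSS-proximity quintiles are both
    computed on the positive set.  Controls are sampled without replacement
    cohort-wide; a cell without enough remaining candidates falls back to the
    nearest non-empty cell (bin-index distance, AF dimension first) and the
    group is flagged relaxed.
    """
    if ratio < 1:
        raise ConfigError("ratio must be >= 1")
    if len(positives) == 0:
        raise ConfigError("no positives to match")
    needed = ratio * len(positives)
    if len(pool) < needed:
        raise InfeasibleMatchError(
            f"pool of {len(pool)} cannot supply {needed} controls "
            f"({ratio} x {len(positives)} positives)"
        )
    overlap = positives.index.intersection(pool.index)
    if len(overlap):
        raise ConfigError(f"pool overlaps positives on {len(overlap)} variant ids")

    af_bounds = af_percentile_bins(positives["AF"], n_bins=n_af_bins)
    tss_bounds = af_percentile_bins(positives["TSS_SCORE"], n_bins=5)

    pool_af = assign_bin(pool["AF"], af_bounds)
    pool_tss = assign_bin(pool["TSS_SCORE"], tss_bounds)
    pos_af = assign_bin(positives["AF"], af_bounds)
    pos_tss = assign_bin(positives["TSS_SCORE"], tss_bounds)

    rng = np.random.default_rng([int(seed), 11])
    # per-cell shuffled queues of pool row positions; popped as consumed
    cells: dict[tuple[int, int], list[int]] = {}
    for i, key in enumerate(zip(pool_af, pool_tss)):
        cells.setdefault(key, []).append(i)
    for key in sorted(cells):
        members = np.array(cells[key])
        rng.shuffle(members)
        cells[key] = list(members)

    rows, relaxed_groups = [], []
    pool_ids = pool.index.to_numpy()
    for g, (pid, a_bin, t_bin) in enumerate(zip(positives.index, pos_af, pos_tss)):
        chosen: list[int] = []
        exact = cells.get((a_bin, t_bin), [])
        take = min(ratio, len(exact))
        chosen.extend(exact[:take])
        cells[(a_bin, t_bin)] = exact[take:]
        relaxed = False
        if len(chosen) < ratio:
            relaxed = True
            # nearest non-empty cells, AF distance dominating
            others = sorted(
                (k for k in cells if cells[k]),
                key=lambda k: (abs(k[0] - a_bin), abs(k[1] - t_bin), k),
            )
            for k in others:
                if len(chosen) >= ratio:
                    break
                q = cells[k]
                take = min(ratio - len(chosen), len(q))
                chosen.extend(q[:take])
                cells[k] = q[take:]
        if len(chosen) < ratio:
            raise InfeasibleMatchError(
                f"exhausted pool while matching positive {pid} "
                f"(cell af_bin={a_bin}, tss_bin={t_bin})"
            )
        if relaxed:
            relaxed_groups.append(pid)
        prow = positives.loc[pid]
        rows.append((pid, pid, "positive", relaxed, prow))
        for i in chosen:
            rows.append((pool_ids[i], pid, "control", relaxed, pool.iloc[i]))

    rec = pd.DataFrame([r[4] for r in rows])
    rec.index = pd.Index([r[0] for r in rows], name="VARIANT_ID")
    rec["GROUP"] = [r[1] for r in rows]
    rec["ROLE"] = [r[2] for r in rows]
    rec["RELAXED"] = [r[3] for r in rows]
    if relaxed_groups:
        warnings.warn(
            f"{len(relaxed_groups)} group(s) required nearest-cell fallback matching",
            stacklevel=2,
        )
    return MatchedCohort(records=rec, ratio=ratio, n_af_bins=n_af_bins, relaxed_groups=relaxed_groups)


def split_holdout(cohort: MatchedCohort, holdout_fraction: float = 0.2, seed: int = 0) -> MatchedCohort:
    """Tag a seeded random ``floor(fraction * n_groups)`` of groups validation.

    Groups stay intact: a positive and all its controls share one split.
    """
    if not 0.0 < holdout_fraction < 1.0:
        raise ConfigError(f"holdout_fraction must lie in (0, 1), got {holdout_fraction}")
    groups = np.array(cohort.groups)
    n_val = int(np.floor(holdout_fraction * len(groups)))
    rng = np.random.default_rng([int(seed), 12])
    val = set(rng.choice(groups, size=n_val, replace=False))
    rec = cohort.records.copy()
    rec["SPLIT"] = np.where(rec["GROUP"].isin(val), "validation", "train")
    return MatchedCohort(
        records=rec, ratio=cohort.ratio, n_af_bins=cohort.n_af_bins, relaxed_groups=list(cohort.relaxed_groups)
    )


def build_alternate_sets(
    candidates: pd.DataFrame,
    ratio: int = 10,
    seed: int = 0,
    holdout_fraction: float = 0.2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Candidate-only training and validation sets with assay negatives.

    Negatives are drawn only from candidates with adjusted p-value above 0.5
    (to limit false negatives) at ``ratio`` negatives per positive.  The
    positives are first split into a training part and a held-out validation
    part; the sampled negatives are disjoint between the two sets.

    ``candidates`` needs a POSITIVE (0/1) and a PADJ column.
    """
    for col in ("POSITIVE", "PADJ"):
        if col not in candidates.columns:
            raise ConfigError(f"candidate table needs a {col} column")
    pos = candidates[candidates["POSITIVE"] == 1]
    eligible = candidates[(candidates["POSITIVE"] == 0) & (candidates["PADJ"] > 0.5)]
    needed = ratio * len(pos)
    if len(eligible) < needed:
        raise InfeasibleMatchError(
            f"only {len(eligible)} eligible negatives (adjusted p > 0.5) for "
            f"{len(pos)} positives at ratio {ratio} ({needed} needed)"
        )
    rng = np.random.default_rng([int(seed), 13])
    neg_ids = rng.choice(eligible.index.to_numpy(), size=needed, replace=False)

    n_val_pos = int(np.floor(holdout_fraction * len(pos)))
    pos_ids = pos.index.to_numpy().copy()
    rng.shuffle(pos_ids)
    val_pos, train_pos = pos_ids[:n_val_pos], pos_ids[n_val_pos:]
    val_neg, train_neg = neg_ids[: ratio * n_val_pos], neg_ids[ratio * n_val_pos :]

    train = candidates.loc[np.concatenate([train_pos, train_neg])]
    validation = candidates.loc[np.concatenate([val_pos, val_neg])]
    return train, validation


def balance_diagnostics(cohort: MatchedCohort, columns=("AF", "TSS_SCORE")) -> pd.DataFrame:
    """Standardized mean difference positives vs controls per column."""
    pos, ctl = cohort.positives(), cohort.controls()
    rows = {}
    for c in columns:
        x, y = pos[c].to_numpy(float), ctl[c].to_numpy(float)
        sd = np.sqrt((x.var(ddof=1) + y.var(ddof=1)) / 2.0)
        rows[c] = {"smd": (x.mean() - y.mean()) / sd if sd > 0 else 0.0}
    return pd.DataFrame(rows).T


def standardized_mean_difference(a, b) -> float:
    """Pooled-SD standardized difference of two samples' means."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    sd = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
    return float((a.mean() - b.mean()) / sd) if sd > 0 else 0.0
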