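"""Synthetic data generators for every pipeline stage.

Real applications of this package consume population allele frequencies
(gnomAD-style), at-site functional score compendia (regBase/Eigen-style raw
and Phred-scaled scores), Roadmap-style non-negative epigenetic marker
tracks, and dense per-position score tracks.  None of those resources can be
shipped, so this module emulates their statistical structure: confounded
allele frequencies, partially informative score columns with missingness,
marker neighborhoods carrying a "valley" pattern (a dip in activating marks
at the element flanked by two peaks), and genome tracks in which positives
clump into active segments.

Every generator is deterministic under ``SynthConfig.seed`` and writes the
latent truth (labels, segment structure) alongside the observables so tests
can do parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as scipy_stats

from .errors import ConfigError

_BASES = np.array(["A", "C", "G", "T"])

# stream ids keep the per-generator RNGs independent of call order
_STREAM_VARIANTS = 1
_STREAM_SCORES = 2
_STREAM_TRACKS = 3
_STREAM_GENOME = 4
_STREAM_ANNOT = 5


@dataclass
class SynthConfig:
    """Knobs of the synthetic cohort generator.

    ``effect_size`` is the mean shift, in within-feature SD units, applied to
    informative features of positive variants.  ``af_confounding`` skews the
    allele-frequency and TSS-proximity distributions of positives toward
    common, TSS-proximal variants — the confounding that matched-control
    selection has to remove.
    """

    n_variants: int = 1000
    positive_fraction: float = 0.1
    n_site_scores: int = 44
    n_tissue_annotations: int = 1016
    n_markers: int = 8
    n_bins: int = 81
    effect_size: float = 0.8
    informative_fraction: float = 0.25
    missing_fraction: float = 0.02
    row_missing_fraction: float = 0.0
    af_confounding: float = 2.0
    clump_rate_active: float = 0.5
    clump_rate_inactive: float = 0.005
    segment_mean_bp: float = 20_000.0
    # valley-pattern fixture geometry (bins)
    valley_flank_offset: int = 5
    valley_peak_width: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_variants", "n_site_scores", "n_markers", "n_bins"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.n_tissue_annotations < 0:
            raise ConfigError("n_tissue_annotations must be >= 0")
        for name in ("positive_fraction", "informative_fraction"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigError(f"{name} must lie in (0, 1), got {v}")
        for name in ("missing_fraction", "row_missing_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ConfigError(f"{name} must lie in [0, 1), got {v}")
        for name in ("clump_rate_active", "clump_rate_inactive"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.effect_size < 0:
            raise ConfigError("effect_size must be non-negative")
        if self.n_bins % 2 == 0:
            raise ConfigError(f"n_bins must be odd so a center bin exists, got {self.n_bins}")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


def generate_variants(config: SynthConfig) -> pd.DataFrame:
    """Draw a variant table with latent labels.

    Allele frequencies follow a log-uniform law on [1e-5, 0.5]; positives are
    stochastically re-weighted toward common AF and toward high (Phred-style)
    TSS-proximity scores, with strength ``af_confounding``.  Exactly
    ``round(n_variants * positive_fraction)`` variants are labeled positive,
    and positives are tagged with one of two synthetic experiment sources
    ("expA", "expB") so source-ordered protocols can be exercised.

    Returns a frame with columns CHROM, POS, REF, ALT, AF, TSS_SCORE, LABEL,
    SOURCE and a variant-id index.
    """
    rng = config.rng(_STREAM_VARIANTS)
    n = config.n_variants
    n_pos = int(round(n * config.positive_fraction))

    label = np.zeros(n, dtype=int)
    label[:n_pos] = 1
    rng.shuffle(label)

    lo, hi = np.log10(1e-5), np.log10(0.5)
    t = rng.uniform(0.0, 1.0, size=n)
    c = config.af_confounding
    # power re-weighting pushes positive AFs toward the common end while
    # keeping the marginal family identical, as quantile matching assumes
    t = np.where(label == 1, t ** (1.0 / (1.0 + c)), t)
    af = 10.0 ** (lo + t * (hi - lo))

    # TSS confounding is piecewise by quintile: positives over-represent the
    # TSS-proximal quintiles with weights (q+1)^c but share the background's
    # conditional law within each quintile — the structure quintile matching
    # is designed to remove
    u = rng.uniform(0.0, 1.0, size=n)
    w = (1.0 + np.arange(5.0)) ** c
    q = rng.choice(5, size=n, p=w / w.sum())
    u = np.where(label == 1, (q + rng.uniform(size=n)) / 5.0, u)
    tss = scipy_stats.gamma.ppf(u, a=2.0, scale=2.0)

    pos = np.sort(rng.choice(np.arange(1, 50 * n + 1), size=n, replace=False))
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4

    source = np.array(["background"] * n, dtype=object)
    pos_rows = np.flatnonzero(label == 1)
    n_a = int(round(0.55 * len(pos_rows)))  # ~55/45 split across the two sources
    source[pos_rows[:n_a]] = "expA"
    source[pos_rows[n_a:]] = "expB"

    df = pd.DataFrame(
        {
            "CHROM": "chr1",
            "POS": pos,
            "REF": _BASES[ref_idx],
            "ALT": _BASES[alt_idx],
            "AF": af,
            "TSS_SCORE": tss,
            "LABEL": label,
            "SOURCE": source,
        }
    )
    df.index = [f"chr1:{p}:{r}:{a}" for p, r, a in zip(df.POS, df.REF, df.ALT)]
    df.index.name = "VARIANT_ID"
    return df


def generate_site_scores(variants: pd.DataFrame, config: SynthConfig) -> pd.DataFrame:
    """Draw the at-site feature matrix (site scores + tissue annotations).

    The first ``round(informative_fraction * n_site_scores)`` site-score
    columns carry the planted signal: the positive-class mean is shifted by
    ``effect_size`` within-column SDs.  Remaining site scores and all tissue
    annotation columns are pure noise.  Half of the site-score columns are
    Phred-style non-negative (gamma noise); tissue annotations are always
    non-negative, mimicking -log10 P-value tracks.  Missing entries are NaN;
    ``variants.attrs``-free, the missingness mask is simply ``df.isna()``.
    Columns flagged Phred-style are recorded in ``df.attrs['phred_columns']``.
    """
    rng = config.rng(_STREAM_SCORES)
    n = len(variants)
    labels = variants["LABEL"].to_numpy()
    n_site, n_tissue = config.n_site_scores, config.n_tissue_annotations
    n_info = int(round(config.informative_fraction * n_site))

    cols, names, phred_cols = [], [], []
    for j in range(n_site):
        phred_style = j % 2 == 1
        if phred_style:
            shape, scale = 2.0, 3.0
            x = rng.gamma(shape=shape, scale=scale, size=n)
            sd = np.sqrt(shape) * scale
        else:
            x = rng.normal(0.0, 1.0, size=n)
            sd = 1.0
        if j < n_info:
            x = x + np.where(labels == 1, config.effect_size * sd, 0.0)
        name = f"SCORE_{j:02d}" + ("_PHRED" if phred_style else "")
        if phred_style:
            phred_cols.append(name)
        names.append(name)
        cols.append(x)
    for j in range(n_tissue):
        names.append(f"TISSUE_{j:04d}")
        cols.append(rng.gamma(shape=1.5, scale=2.0, size=n))

    mat = np.column_stack(cols) if cols else np.empty((n, 0))
    if config.missing_fraction > 0 and mat.size:
        mask = rng.uniform(size=mat.shape) < config.missing_fraction
        mat[mask] = np.nan
    if config.row_missing_fraction > 0 and mat.size:
        rows = rng.uniform(size=n) < config.row_missing_fraction
        mat[rows, :] = np.nan

    df = pd.DataFrame(mat, index=variants.index, columns=names)
    df.attrs["phred_columns"] = phred_cols + [c for c in names if c.startswith("TISSUE_")]
    df.attrs["n_informative"] = n_info
    return df


def _valley_pattern(config: SynthConfig) -> np.ndarray:
    """Center dip flanked by two peaks, on an odd-length bin axis."""
    bins = np.arange(config.n_bins)
    center = config.n_bins // 2
    w = config.valley_peak_width / 2.0
    peaks = np.exp(-0.5 * ((bins - (center - config.valley_flank_offset)) / w) ** 2)
    peaks = peaks + np.exp(-0.5 * ((bins - (center + config.valley_flank_offset)) / w) ** 2)
    dip = -0.5 * np.exp(-0.5 * ((bins - center) / w) ** 2)
    return peaks + dip


def generate_neighborhood_tracks(variants: pd.DataFrame, config: SynthConfig) -> np.ndarray:
    """Draw non-negative marker neighborhoods, shape (n, n_markers, n_bins).

    Background bins are gamma noise on every channel.  Positives additionally
    receive the valley pattern — flanking peaks around a central dip — on the
    first half of the marker channels (the "activating" marks), with
    amplitude ``effect_size`` noise-SDs.  Values are clipped at zero.
    """
    rng = config.rng(_STREAM_TRACKS)
    n = len(variants)
    labels = variants["LABEL"].to_numpy()
    shape, scale = 2.0, 1.0
    arr = rng.gamma(shape=shape, scale=scale, size=(n, config.n_markers, config.n_bins))
    amp = config.effect_size * np.sqrt(shape) * scale
    if amp > 0:
        pattern = amp * _valley_pattern(config)
        n_act = max(1, config.n_markers // 2)
        arr[labels == 1, :n_act, :] += pattern[None, None, :]
    return np.clip(arr, 0.0, None)


@dataclass
class GenomeTrack:
    """A dense per-position score track with its latent truth."""

    scores: np.ndarray
    latent_positive: np.ndarray
    active_segment: np.ndarray
    threshold: float = field(default=0.0)

    def __len__(self) -> int:
        return len(self.scores)


def generate_genome_track(region_length_bp: int, config: SynthConfig) -> GenomeTrack:
    """Simulate a dense score track over a region with clumped positives.

    The region is partitioned into alternating active/inactive segments with
    exponential lengths (mean ``segment_mean_bp``).  Each position is latently
    positive with probability ``clump_rate_active`` inside active segments and
    ``clump_rate_inactive`` elsewhere.  Scores are drawn so that thresholding
    at the empirical top-q quantile (q = realized positive fraction) recovers
    the latent indicator; the suggested threshold is stored on the result.
    """
    if region_length_bp < 1000 or region_length_bp % 1000 != 0:
        raise ConfigError("region_length_bp must be a positive multiple of 1000")
    rng = config.rng(_STREAM_GENOME)

    active = np.zeros(region_length_bp, dtype=bool)
    pos = 0
    state = bool(rng.integers(0, 2))
    while pos < region_length_bp:
        seg = max(1, int(rng.exponential(config.segment_mean_bp)))
        active[pos : pos + seg] = state
        state = not state
        pos += seg

    rate = np.where(active, config.clump_rate_active, config.clump_rate_inactive)
    latent = rng.uniform(size=region_length_bp) < rate
    # positives occupy the top score band, negatives the rest
    scores = np.where(
        latent,
        0.95 + 0.05 * rng.uniform(size=region_length_bp),
        0.95 * rng.uniform(size=region_length_bp),
    )
    frac = latent.mean()
    thr = float(np.quantile(scores, 1.0 - frac)) if 0 < frac < 1 else (0.95 if frac == 0 else 0.0)
    return GenomeTrack(scores=scores, latent_positive=latent, active_segment=active, threshold=thr)


def generate_annotation_table(
    variants: pd.DataFrame,
    n_quant: int,
    n_binary: int,
    config: SynthConfig,
    quant_effect: float = 0.0,
    binary_odds_ratio: float = 1.0,
) -> pd.DataFrame:
    """Draw a per-variant annotation table for group-comparison tests.

    Quantitative columns are unit-normal with the positive-class mean shifted
    by ``quant_effect`` SDs; binary columns have baseline prevalence 0.3 with
    the positive-class odds multiplied by ``binary_odds_ratio``.
    """
    if n_quant < 0 or n_binary < 0:
        raise ConfigError("annotation column counts must be >= 0")
    rng = config.rng(_STREAM_ANNOT)
    n = len(variants)
    labels = variants["LABEL"].to_numpy()
    data = {}
    for j in range(n_quant):
        data[f"QUANT_{j:02d}"] = rng.normal(0.0, 1.0, size=n) + quant_effect * (labels == 1)
    base_p = 0.3
    odds = base_p / (1 - base_p) * binary_odds_ratio
    p_pos = odds / (1 + odds)
    for j in range(n_binary):
        p = np.where(labels == 1, p_pos, base_p)
        data[f"BIN_{j:02d}"] = (rng.uniform(size=n) < p).astype(int)
    return pd.DataFrame(data, index=variants.index)
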