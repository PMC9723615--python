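"""Per-variant feature assembly and cleaning.

Each variant's model input is a :class:`FeatureBundle`: a fixed-length
at-site score vector (functional scores plus tissue annotations) and an
``n_markers x n_bins`` neighborhood array of local epigenetic marks at 25-bp
resolution with the variant at the center bin.  Cleaning rules: rows that
share a variant key (allelic multiplicates) are averaged column-wise;
variants with an entirely missing score row (or no neighborhood track) are
excluded with a reason code; partially missing entries are imputed with the
training-set feature median.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError


@dataclass
class FeatureBundle:
    variant_id: str
    site_vector: np.ndarray  # (L_site,)
    neighborhood: np.ndarray  # (n_markers, n_bins)

    def __eq__(self, other) -> bool:  # bit-exact, for round-trip checks
        return (
            isinstance(other, FeatureBundle)
            and self.variant_id == other.variant_id
            and np.array_equal(self.site_vector, other.site_vector)
            and np.array_equal(self.neighborhood, other.neighborhood)
        )


def collapse_allelic_duplicates(score_table: pd.DataFrame) -> pd.DataFrame:
    """Average rows that share a variant key, ignoring missing entries.

    A column missing in every duplicate row stays missing.  Single rows pass
    through unchanged; output row order follows first appearance.
    """
    if score_table.index.has_duplicates:
        collapsed = score_table.groupby(level=0, sort=False).mean()
        collapsed.attrs = dict(score_table.attrs)
        return collapsed
    return score_table


def fit_imputer(train_scores: pd.DataFrame) -> pd.Series:
    """Per-column medians of the training score table (NaNs ignored)."""
    return train_scores.median(axis=0, skipna=True)


def assemble_features(
    variants: pd.DataFrame,
    score_table: pd.DataFrame,
    track_store,
    medians: pd.Series | None = None,
) -> tuple[list[FeatureBundle], pd.DataFrame]:
    """Build one bundle per variant, excluding unusable variants.

    ``track_store`` maps variant id -> (n_markers, n_bins) array (a dict, or
    an ndarray aligned row-wise with ``variants``).  Exclusion reasons:
    ``no_scores`` (score row absent or entirely missing) and ``no_track``.
    Partial missingness is imputed with ``medians`` (fall back to the
    column medians of ``score_table`` itself when not supplied).

    Returns ``(bundles, exclusions)`` where exclusions has columns
    VARIANT_ID, REASON.
    """
    if isinstance(track_store, np.ndarray):
        if len(track_store) != len(variants):
            raise ConfigError("track array length does not match variant table")
        track_store = {vid: track_store[i] for i, vid in enumerate(variants.index)}
    if medians is None:
        medians = fit_imputer(score_table)

    bundles, excluded = [], []
    med = medians.to_numpy(dtype=float)
    for vid in variants.index:
        if vid not in score_table.index:
            excluded.append((vid, "no_scores"))
            continue
        row = score_table.loc[vid].to_numpy(dtype=float)
        if np.isnan(row).all():
            excluded.append((vid, "no_scores"))
            continue
        if vid not in track_store:
            excluded.append((vid, "no_track"))
            continue
        nan = np.isnan(row)
        if nan.any():
            row = np.where(nan, med, row)
        bundles.append(
            FeatureBundle(
                variant_id=vid,
                site_vector=row,
                neighborhood=np.asarray(track_store[vid], dtype=float),
            )
        )
    exclusions = pd.DataFrame(excluded, columns=["VARIANT_ID", "REASON"])
    return bundles, exclusions


def stack_bundles(bundles: list[FeatureBundle]) -> tuple[np.ndarray, np.ndarray]:
    """(site matrix (n, L_site), neighborhood array (n, markers, bins))."""
    if not bundles:
        raise ConfigError("no bundles to stack")
    return (
        np.stack([b.site_vector for b in bundles]),
        np.stack([b.neighborhood for b in bundles]),
    )


class Standardizer:
    """Affine per-feature standardization fitted on the training split.

    Site features are standardized per column; neighborhoods per marker
    channel (one mean/SD per marker across all bins and variants).  Constant
    features map to 0.  Raw Phred-scaled scores, P-value annotations and
    model scores live on wildly different scales, so this is on by default
    upstream of the classifier, but it is a separate, optional step.
    """

    def __init__(self) -> None:
        self._fitted = False

    def fit(self, site: np.ndarray, neighborhood: np.ndarray) -> "Standardizer":
        self.site_mean_ = site.mean(axis=0)
        self.site_sd_ = site.std(axis=0)
        self.nbhd_mean_ = neighborhood.mean(axis=(0, 2))
        self.nbhd_sd_ = neighborhood.std(axis=(0, 2))
        self._fitted = True
        return self

    def transform(self, site: np.ndarray, neighborhood: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if not self._fitted:
            raise ConfigError("standardizer not fitted; call fit on the training split first")
        s_sd = np.where(self.site_sd_ > 0, self.site_sd_, 1.0)
        site_z = (site - self.site_mean_) / s_sd
        site_z[:, self.site_sd_ == 0] = 0.0
        n_sd = np.where(self.nbhd_sd_ > 0, self.nbhd_sd_, 1.0)
        nb_z = (neighborhood - self.nbhd_mean_[None, :, None]) / n_sd[None, :, None]
        nb_z[:, self.nbhd_sd_ == 0, :] = 0.0
        return site_z, nb_z

    def fit_transform(self, site, neighborhood):
        return self.fit(site, neighborhood).transform(site, neighborhood)

    def to_dict(self) -> dict:
        return {
            "site_mean": self.site_mean_.tolist(),
            "site_sd": self.site_sd_.tolist(),
            "nbhd_mean": self.nbhd_mean_.tolist(),
            "nbhd_sd": self.nbhd_sd_.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Standardizer":
        s = cls()
        s.site_mean_ = np.asarray(d["site_mean"], float)
        s.site_sd_ = np.asarray(d["site_sd"], float)
        s.nbhd_mean_ = np.asarray(d["nbhd_mean"], float)
        s.nbhd_sd_ = np.asarray(d["nbhd_sd"], float)
        s._fitted = True
        return s
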