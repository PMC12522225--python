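"""End-motif matrix algebra.

A cfDNA fragment's terminal k nucleotides (the *end motif*, here k=4) are
shaped by the nucleases that release the fragment into plasma; tumours shift
the relative usage of the 256 possible 4-mers.  This module holds the fixed
motif index space and the two normalisation steps applied to raw motif
counts before any modelling:

1. ratio-to-average: each motif count is divided by the mean count over all
   256 motifs, so every sample row averages to 1 regardless of depth;
2. z-scaling: per-motif standardisation with mean/sd estimated on a
   designated fitting set (normally the training split) and frozen.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

ALPHABET = "ACGT"


def enumerate_motifs(k: int = 4) -> list[str]:
    """All 4^k DNA k-mers in lexicographic order (AA..A first, TT..T last)."""
    if not 1 <= int(k) <= 8:
        raise ValueError(f"k must be in [1, 8], got {k}")
    return ["".join(p) for p in itertools.product(ALPHABET, repeat=int(k))]


#: the canonical 256-motif axis used by every matrix in the package
MOTIFS_4MER: tuple[str, ...] = tuple(enumerate_motifs(4))

_MOTIF_INDEX = {m: i for i, m in enumerate(MOTIFS_4MER)}


def motif_index(motif: str) -> int:
    """Position of ``motif`` on the fixed lexicographic 4-mer axis."""
    return _MOTIF_INDEX[motif]


def _check_motif_axis(columns) -> None:
    if list(columns) != list(MOTIFS_4MER):
        raise ValueError(
            "motif axis mismatch: expected the 256 4-mers in lexicographic "
            f"order, got {len(columns)} columns"
        )


def counts_to_ratios(counts: pd.DataFrame) -> pd.DataFrame:
    """Convert motif counts to ratio-to-average values.

    For a row with counts c_m the ratio is r_m = c_m / (sum(c)/256)
    = 256 * c_m / sum(c); each converted row has mean exactly 1 and sums
    to 256.  Rows with a zero total carry no motif information and are
    dropped with a warning rather than silently turned into NaN.
    """
    _check_motif_axis(counts.columns)
    totals = counts.sum(axis=1).to_numpy(dtype=float)
    usable = totals > 0
    if not usable.all():
        import warnings

        bad = list(counts.index[~usable])
        warnings.warn(
            f"dropping {len(bad)} zero-total sample row(s): {bad[:5]}",
            stacklevel=2,
        )
    out = counts.loc[usable].astype(float)
    out = out.mul(len(MOTIFS_4MER) / totals[usable], axis=0)
    return out


class MotifZScaler(BaseEstimator, TransformerMixin):
    """Per-motif z-scaling with statistics frozen on a fitting set.

    Means and standard deviations (sample sd, ``ddof=1``) are estimated on
    the rows passed to :meth:`fit` — in the screening workflow, the training
    split only — and applied unchanged to validation/test rows.  Motifs that
    are constant on the fitting set (sd = 0) are mapped to z = 0 and listed
    in ``constant_motifs_`` instead of being dropped, so the 256-column
    geometry stays fixed for PCA downstream.

    Attributes
    ----------
    mean_ : ndarray of shape (256,)
    scale_ : ndarray of shape (256,)
        Fitting-set sd per motif; 0 entries are kept as recorded but the
        transform divides by 1 there.
    constant_motifs_ : list of str
    n_fit_samples_ : int
    """

    def fit(self, X: pd.DataFrame, y=None) -> "MotifZScaler":
        _check_motif_axis(X.columns)
        if len(X) < 2:
            raise ValueError(f"need >= 2 fitting samples, got {len(X)}")
        values = X.to_numpy(dtype=float)
        self.mean_ = values.mean(axis=0)
        self.scale_ = values.std(axis=0, ddof=1)
        const = self.scale_ == 0.0
        self.constant_motifs_ = [m for m, c in zip(MOTIFS_4MER, const) if c]
        self.n_fit_samples_ = len(X)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "mean_")
        _check_motif_axis(X.columns)
        denom = np.where(self.scale_ > 0, self.scale_, 1.0)
        z = (X.to_numpy(dtype=float) - self.mean_) / denom
        z[:, self.scale_ == 0.0] = 0.0
        return pd.DataFrame(z, index=X.index, columns=list(MOTIFS_4MER))

    def inverse_transform(self, Z: pd.DataFrame) -> pd.DataFrame:
        """Undo the scaling for non-constant motifs (constant ones return the
        fitting-set mean)."""
        check_is_fitted(self, "mean_")
        _check_motif_axis(Z.columns)
        r = Z.to_numpy(dtype=float) * self.scale_ + self.mean_
        return pd.DataFrame(r, index=Z.index, columns=list(MOTIFS_4MER))

    def to_json(self) -> str:
        check_is_fitted(self, "mean_")
        return json.dumps(
            {
                "mean": self.mean_.tolist(),
                "scale": self.scale_.tolist(),
                "constant_motifs": self.constant_motifs_,
                "n_fit_samples": self.n_fit_samples_,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "MotifZScaler":
        payload = json.loads(text)
        obj = cls()
        obj.mean_ = np.asarray(payload["mean"], dtype=float)
        obj.scale_ = np.asarray(payload["scale"], dtype=float)
        obj.constant_motifs_ = list(payload["constant_motifs"])
        obj.n_fit_samples_ = int(payload["n_fit_samples"])
        return obj


@dataclass
class ScalerStats:
    """Functional view of fitted scaler statistics (mean/sd per motif)."""

    mean: np.ndarray
    sd: np.ndarray
    constant_motifs: list[str] = field(default_factory=list)
    n_fit_samples: int = 0


def fit_zscore(matrix: pd.DataFrame, fitting_ids=None) -> ScalerStats:
    """Estimate per-motif mean and sample sd on ``fitting_ids`` rows.

    Thin functional wrapper over :class:`MotifZScaler`.
    """
    subset = matrix if fitting_ids is None else matrix.loc[list(fitting_ids)]
    scaler = MotifZScaler().fit(subset)
    return ScalerStats(
        mean=scaler.mean_,
        sd=scaler.scale_,
        constant_motifs=scaler.constant_motifs_,
        n_fit_samples=scaler.n_fit_samples_,
    )


def apply_zscore(matrix: pd.DataFrame, stats: ScalerStats) -> pd.DataFrame:
    """Apply frozen z-scaling statistics to ``matrix`` rows."""
    scaler = MotifZScaler()
    scaler.mean_ = np.asarray(stats.mean, dtype=float)
    scaler.scale_ = np.asarray(stats.sd, dtype=float)
    scaler.constant_motifs_ = list(stats.constant_motifs)
    scaler.n_fit_samples_ = stats.n_fit_samples
    return scaler.transform(matrix)
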