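"""Regression and virtual-screening metrics.

Regression: MSE, concordance index (CI), R^2, Spearman, Pearson.
Screening: enrichment factor EF@k%, precision@n, and BEDROC(alpha), the
exponentially early-weighted enrichment score of Truchon & Bayly.

Ranking conventions: compounds are ranked by *descending* predicted score;
score ties are broken by the stable original index so EF/BEDROC are
deterministic.  CI gives tied predictions 0.5 credit, the standard
concordance convention (a constant predictor scores 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "MetricsReport",
    "RankedScreen",
    "bedroc",
    "concordance_index",
    "enrichment_factor",
    "mse",
    "pearson",
    "precision_at_n",
    "r_squared",
    "regression_report",
    "spearman",
]

DEFAULT_BEDROC_ALPHA = 80.5


def _pair(y, yhat) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=np.float64)
    yhat = np.asarray(yhat, dtype=np.float64)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError(f"need equal-length 1-D vectors, got {y.shape} vs {yhat.shape}")
    if y.size == 0:
        raise ValueError("empty input")
    return y, yhat


def mse(y, yhat) -> float:
    """Mean squared error (1/N) * sum (y_i - yhat_i)^2."""
    y, yhat = _pair(y, yhat)
    return float(np.mean((y - yhat) ** 2))


def concordance_index(y, yhat) -> float:
    """Fraction of comparable pairs (y_i > y_j) ranked concordantly.

    Tied predictions count 0.5.  Raises if all true values are tied
    (no comparable pair exists).
    """
    y, yhat = _pair(y, yhat)
    # pairwise sign matrices; n is small enough that O(n^2) memory is fine
    gt = y[:, None] > y[None, :]
    z = int(gt.sum())
    if z == 0:
        raise ValueError("concordance index undefined: all true values tied")
    conc = (yhat[:, None] > yhat[None, :])[gt].sum()
    ties = (yhat[:, None] == yhat[None, :])[gt].sum()
    return float((conc + 0.5 * ties) / z)


def r_squared(y, yhat) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot."""
    y, yhat = _pair(y, yhat)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 undefined for constant true values")
    return float(1.0 - np.sum((y - yhat) ** 2) / ss_tot)


def spearman(y, yhat) -> float:
    """Spearman rank correlation (average ranks on ties, Pearson on ranks)."""
    y, yhat = _pair(y, yhat)
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    if np.all(y == y[0]) or np.all(yhat == yhat[0]):
        raise ValueError("Spearman undefined for constant input")
    return float(stats.spearmanr(y, yhat).statistic)


def pearson(y, yhat) -> float:
    """Pearson linear correlation coefficient."""
    y, yhat = _pair(y, yhat)
    # exact-equality test: a constant vector can still have a 1-ulp nonzero
    # std through mean rounding, which would slip NaN past an std-based guard
    if y.size < 2 or np.all(y == y[0]) or np.all(yhat == yhat[0]):
        raise ValueError("Pearson undefined for constant input")
    return float(stats.pearsonr(y, yhat).statistic)


@dataclass(frozen=True)
class RankedScreen:
    """A scored screening deck: predicted affinities plus active flags."""

    scores: np.ndarray
    labels: np.ndarray  # bool, True = active

    def __post_init__(self):
        scores = np.asarray(self.scores, dtype=np.float64)
        labels = np.asarray(self.labels, dtype=bool)
        if scores.shape != labels.shape or scores.ndim != 1:
            raise ValueError("scores and labels must be equal-length 1-D vectors")
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "labels", labels)

    @property
    def n(self) -> int:
        return self.scores.size

    @property
    def n_actives(self) -> int:
        return int(self.labels.sum())

    @property
    def ranking(self) -> np.ndarray:
        """Indices by descending score; ties broken by original index."""
        return np.argsort(-self.scores, kind="stable")

    def ranked_labels(self) -> np.ndarray:
        return self.labels[self.ranking]


def enrichment_factor(screen: RankedScreen, k_percent: float) -> float:
    """EF@k% = actives in the top ceil(k% * N) over (k/100) * N_actives."""
    if not 0 < k_percent <= 100:
        raise ValueError("k_percent must be in (0, 100]")
    if screen.n_actives == 0:
        raise ValueError("enrichment factor undefined with no actives")
    top = int(np.ceil(k_percent / 100.0 * screen.n))
    hits = int(screen.ranked_labels()[:top].sum())
    return float(hits / (k_percent / 100.0 * screen.n_actives))


def precision_at_n(screen: RankedScreen, n: int) -> float:
    """Fraction of actives among the top-n ranked compounds."""
    if not 1 <= n <= screen.n:
        raise ValueError(f"n must be in [1, {screen.n}]")
    return float(screen.ranked_labels()[:n].sum() / n)


def bedroc(screen: RankedScreen, alpha: float = DEFAULT_BEDROC_ALPHA) -> float:
    """Boltzmann-enhanced discrimination of ROC, in [0, 1].

    Exponentially weights early ranks; alpha = 80.5 concentrates ~80% of the
    weight in the top ~2% of the list.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    n, n_act = screen.n, screen.n_actives
    if not 0 < n_act < n:
        raise ValueError("BEDROC needs both actives and inactives")
    ra = n_act / n
    ranks = np.flatnonzero(screen.ranked_labels()) + 1  # 1-based ranks of actives
    s = float(np.sum(np.exp(-alpha * ranks / n)))
    rie_denom = ra * (1.0 - np.exp(-alpha)) / (np.exp(alpha / n) - 1.0)
    factor = ra * np.sinh(alpha / 2.0) / (np.cosh(alpha / 2.0) - np.cosh(alpha / 2.0 - alpha * ra))
    return float(s / rie_denom * factor + 1.0 / (1.0 - np.exp(alpha * (1.0 - ra))))


@dataclass(frozen=True)
class ScreeningBlock:
    ef: dict[float, float] = field(default_factory=dict)  # k% -> EF
    precision: dict[int, float] = field(default_factory=dict)  # n -> precision
    bedroc: float | None = None
    bedroc_alpha: float = DEFAULT_BEDROC_ALPHA


@dataclass(frozen=True)
class MetricsReport:
    """Bundle of regression metrics, with an optional screening block."""

    mse: float
    ci: float | None
    r2: float | None
    spearman: float | None
    pearson: float | None
    screening: ScreeningBlock | None = None

    def to_dict(self) -> dict:
        d = {
            "mse": self.mse,
            "ci": self.ci,
            "r2": self.r2,
            "spearman": self.spearman,
            "pearson": self.pearson,
        }
        if self.screening is not None:
            d["ef"] = {str(k): v for k, v in self.screening.ef.items()}
            d["precision"] = {str(k): v for k, v in self.screening.precision.items()}
            d["bedroc"] = self.screening.bedroc
            d["bedroc_alpha"] = self.screening.bedroc_alpha
        return d


def _maybe(fn, y, yhat):
    try:
        return fn(y, yhat)
    except ValueError:
        return None


def regression_report(y, yhat, screen: RankedScreen | None = None,
                      ef_percents: Sequence[float] = (1.0, 5.0),
                      precision_ns: Sequence[int] = (10, 20),
                      bedroc_alpha: float = DEFAULT_BEDROC_ALPHA) -> MetricsReport:
    """All five regression metrics (degenerate ones reported as None)."""
    block = None
    if screen is not None:
        block = ScreeningBlock(
            ef={k: enrichment_factor(screen, k) for k in ef_percents if int(np.ceil(k / 100 * screen.n)) >= 1},
            precision={n: precision_at_n(screen, n) for n in precision_ns if n <= screen.n},
            bedroc=bedroc(screen, bedroc_alpha),
            bedroc_alpha=bedroc_alpha,
        )
    return MetricsReport(
        mse=mse(y, yhat),
        ci=_maybe(concordance_index, y, yhat),
        r2=_maybe(r_squared, y, yhat),
        spearman=_maybe(spearman, y, yhat),
        pearson=_maybe(pearson, y, yhat),
        screening=block,
    )
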