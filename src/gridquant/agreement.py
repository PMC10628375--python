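"""Inter-observer agreement on case-level scores.

Two pathologists score the same cases; agreement is summarised by raw
percent agreement and by Cohen's unweighted kappa,

    kappa = (p_o - p_e) / (1 - p_e),

where p_o is the observed proportion of exact matches and
p_e = sum_k a_k * b_k is the agreement expected by chance from the two
raters' marginal score frequencies.  Kappa values are mapped onto Cohen's
verbal bands (none to slight / fair / moderate / substantial / almost
perfect).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError

#: Cohen's interpretation bands: (upper edge inclusive, label).
KAPPA_BANDS = (
    (0.0, "no agreement"),
    (0.20, "none to slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.00, "almost perfect"),
)


@dataclass(frozen=True)
class RatingPair:
    """Two raters' scores over the same cases, in the same order."""

    ratings_a: tuple
    ratings_b: tuple
    categories: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "ratings_a", tuple(self.ratings_a))
        object.__setattr__(self, "ratings_b", tuple(self.ratings_b))
        object.__setattr__(self, "categories", tuple(self.categories))
        if len(self.ratings_a) != len(self.ratings_b):
            raise InvalidParameterError(
                f"rating lists differ in length: {len(self.ratings_a)} vs {len(self.ratings_b)}"
            )
        if len(self.ratings_a) < 2:
            raise InvalidParameterError("need at least 2 rated cases")
        cats = set(self.categories)
        if len(cats) < 1:
            raise InvalidParameterError("category set is empty")
        bad = [r for r in self.ratings_a + self.ratings_b if r not in cats]
        if bad:
            raise InvalidParameterError(f"ratings outside the category set: {sorted(set(bad))}")

    @property
    def n_items(self) -> int:
        return len(self.ratings_a)

    def contingency(self) -> np.ndarray:
        """K x K contingency table, rows = rater A, cols = rater B."""
        idx = {c: i for i, c in enumerate(self.categories)}
        table = np.zeros((len(self.categories),) * 2, dtype=np.int64)
        for a, b in zip(self.ratings_a, self.ratings_b):
            table[idx[a], idx[b]] += 1
        return table


@dataclass(frozen=True)
class AgreementResult:
    kappa: float
    percent_agreement: float
    interpretation: str
    n_items: int
    kappa_degenerate: bool = False  # both raters constant and identical

    def to_dict(self) -> dict:
        return {
            "kappa": self.kappa,
            "percent_agreement": self.percent_agreement,
            "interpretation": self.interpretation,
            "n": self.n_items,
            "kappa_degenerate": self.kappa_degenerate,
        }


def percent_agreement(pair: RatingPair) -> float:
    """100 * (exact matches) / n."""
    matches = sum(a == b for a, b in zip(pair.ratings_a, pair.ratings_b))
    return 100.0 * matches / pair.n_items


def cohen_kappa(pair: RatingPair, weights: str | None = None) -> float:
    """Cohen's kappa for two raters; unweighted by default.

    ``weights`` may be "linear" or "quadratic" for the weighted variant
    (categories are then treated as ordered, equally spaced); the default
    ``None`` is the plain unweighted statistic.

    When both raters are constant and identical, p_e = 1 and the usual
    formula is 0/0; the pair agrees perfectly, so 1.0 is returned with a
    warning.
    """
    table = pair.contingency().astype(float)
    n = table.sum()
    k = table.shape[0]
    marg_a = table.sum(axis=1) / n
    marg_b = table.sum(axis=0) / n

    if weights is None:
        w = 1.0 - np.eye(k)  # disagreement weight matrix
    elif weights == "linear":
        i, j = np.indices((k, k))
        w = np.abs(i - j) / max(k - 1, 1)
    elif weights == "quadratic":
        i, j = np.indices((k, k))
        w = ((i - j) / max(k - 1, 1)) ** 2
    else:
        raise InvalidParameterError(f"weights must be None, 'linear' or 'quadratic', got {weights!r}")

    d_o = (w * table / n).sum()
    d_e = (w * np.outer(marg_a, marg_b)).sum()
    if d_e == 0.0:
        warnings.warn(
            "kappa is 0/0 (both raters constant and identical); returning 1.0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 1.0
    return 1.0 - d_o / d_e


def kappa_standard_error(pair: RatingPair) -> float:
    """Large-sample normal-approximation standard error of unweighted kappa,
    SE = sqrt(p_o (1 - p_o) / (n (1 - p_e)^2)).

    Offered as an optional extra for rough confidence intervals; it is not
    part of the grid method itself.
    """
    table = pair.contingency().astype(float)
    n = table.sum()
    p_o = np.trace(table) / n
    marg_a = table.sum(axis=1) / n
    marg_b = table.sum(axis=0) / n
    p_e = float(marg_a @ marg_b)
    if p_e == 1.0:
        return 0.0
    return float(np.sqrt(p_o * (1 - p_o) / (n * (1 - p_e) ** 2)))


def interpret_kappa(k: float) -> str:
    """Cohen's verbal band for a kappa value.

    <= 0 is "no agreement"; (0, 0.20] "none to slight"; (0.20, 0.40] "fair";
    (0.40, 0.60] "moderate"; (0.60, 0.80] "substantial"; (0.80, 1.0]
    "almost perfect".
    """
    if not -1.0 <= k <= 1.0:
        raise InvalidParameterError(f"kappa must be in [-1, 1], got {k}")
    for upper, label in KAPPA_BANDS:
        if k <= upper:
            return label
    raise AssertionError("unreachable")


def analyze_agreement(pair: RatingPair) -> AgreementResult:
    """Full agreement summary for a pair of raters."""
    table = pair.contingency().astype(float)
    marg_a = table.sum(axis=1) / pair.n_items
    marg_b = table.sum(axis=0) / pair.n_items
    degenerate = float(marg_a @ marg_b) == 1.0
    with warnings.catch_warnings():
        if degenerate:
            warnings.simplefilter("ignore", RuntimeWarning)
        kappa = cohen_kappa(pair)
    return AgreementResult(
        kappa=kappa,
        percent_agreement=percent_agreement(pair),
        interpretation=interpret_kappa(kappa),
        n_items=pair.n_items,
        kappa_degenerate=degenerate,
    )
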