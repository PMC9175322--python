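"""Abridged life tables, life expectancy and lifespan inequality.

A period life table converts an age schedule of central death rates m into
the survival experience of a synthetic cohort of ``radix`` newborns. The
m -> q conversion for closed intervals uses the Greville relation

    q = n*m / (1 + (n - a)*m)

where a (nax) is the average time lived in the interval by those dying in
it. The terminal open interval has q = 1 and exposure L = l/m (constant
hazard beyond the last bound).

Life expectancy at birth (e0) is T0 / radix. Lifespan inequality (LI) is
the standard deviation of the life-table distribution of age at death:
closed intervals contribute a point mass d at age x + a; the open interval
contributes its mass at mean age x + 1/m with an extra within-interval
variance of (1/m)^2 from the exponential-tail assumption. The SD is taken
unconditionally from birth, about the mean age at death (= e0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ages import LADDER_LOWER, LADDER_WIDTH

logger = logging.getLogger("lifegap")

LIFETABLE_COLUMNS = ["x", "n", "m", "a", "q", "l", "d", "L", "T", "e"]

_CANON_X = np.asarray(LADDER_LOWER, dtype=float)
_CANON_N = np.asarray(LADDER_WIDTH, dtype=float)

#: Coale-Demeny two-branch a0 coefficients keyed on the infant death rate.
_A0_RULES = {
    "male": (0.107, 0.330, 0.045, 2.684),
    "female": (0.107, 0.350, 0.053, 2.800),
}


def _a0(m0: float, sex: str | None) -> float:
    """Average age at death of infants dying in [0,1), from m0.

    Two-branch demography-text approximation; with ``sex=None`` the male
    and female coefficients are averaged.
    """
    if sex is None:
        return 0.5 * (_a0(m0, "male") + _a0(m0, "female"))
    thresh, high, c0, c1 = _A0_RULES[sex]
    return high if m0 >= thresh else c0 + c1 * m0


def default_ax(
    x: np.ndarray, n: np.ndarray, m: np.ndarray, ax_rule: str, sex: str | None
) -> np.ndarray:
    """nax values for every interval; the open interval gets a = 1/m."""
    a = np.where(np.isinf(n), 0.0, n / 2.0)
    if ax_rule == "standard":
        for i in range(len(x)):
            if np.isinf(n[i]):
                continue
            if x[i] == 0 and n[i] == 1:
                a[i] = _a0(m[i], sex)
            elif x[i] == 1 and n[i] == 4:
                a[i] = 1.5
    elif ax_rule != "midpoint":
        raise ValueError(f"unknown ax_rule {ax_rule!r}; use 'standard' or 'midpoint'")
    if m[-1] > 0:
        a[-1] = 1.0 / m[-1]
    return a


def build_lifetable(
    m: np.ndarray,
    *,
    x: np.ndarray | None = None,
    n: np.ndarray | None = None,
    radix: float = 100_000.0,
    ax_rule: str = "standard",
    sex: str | None = None,
) -> pd.DataFrame:
    """Build an abridged life table from central death rates.

    Parameters
    ----------
    m : array
        Central death rates per person-year, one per age interval.
    x, n : arrays, optional
        Interval lower bounds and widths. Default: the canonical 19-group
        ladder. The last width must be infinite (open interval).
    radix : float
        Starting cohort size l(0); results e0 and SD are radix-invariant.
    ax_rule : {"standard", "midpoint"}
        "standard": infant a0 from the two-branch m0 rule, a = 1.5 on
        [1,5), n/2 elsewhere. "midpoint": a = n/2 everywhere.
    sex : {"male", "female", None}
        Selects the a0 coefficient branch; None averages the sexes.
    """
    cols = _lifetable_arrays(m, x=x, n=n, radix=radix, ax_rule=ax_rule, sex=sex)
    return pd.DataFrame(dict(zip(LIFETABLE_COLUMNS, cols)),
                        columns=LIFETABLE_COLUMNS)


def _lifetable_arrays(
    m,
    *,
    x=None,
    n=None,
    radix: float = 100_000.0,
    ax_rule: str = "standard",
    sex: str | None = None,
) -> tuple[np.ndarray, ...]:
    """Numeric core of :func:`build_lifetable`; returns the column arrays
    (x, n, m, a, q, l, d, L, T, e) without DataFrame overhead."""
    m = np.asarray(m, dtype=float)
    if x is None or n is None:
        if len(m) != len(LADDER_LOWER):
            raise ValueError(
                f"expected {len(LADDER_LOWER)} canonical-ladder rates, got {len(m)}"
            )
        x = _CANON_X
        n = _CANON_N
    else:
        x = np.asarray(x, dtype=float)
        n = np.asarray(n, dtype=float)
    if not (len(x) == len(n) == len(m)):
        raise ValueError("x, n, m must have equal length")
    if not np.isinf(n[-1]) or np.isinf(n[:-1]).any():
        raise ValueError("exactly the last interval must be open (infinite width)")
    if not np.all(np.isfinite(m)):
        raise ValueError("death rates must be finite")
    if (m < 0).any():
        raise ValueError(f"negative death rates at indices {np.flatnonzero(m < 0)}")
    if m[-1] <= 0:
        raise ValueError(
            "life table cannot close: open-interval all-cause rate must be > 0"
        )

    a = default_ax(x, n, m, ax_rule, sex)

    k = len(m)
    q = np.empty(k)
    q[:-1] = n[:-1] * m[:-1] / (1.0 + (n[:-1] - a[:-1]) * m[:-1])
    if (q[:-1] > 1.0).any() or (q[:-1] < 0.0).any():
        logger.warning(
            "clamped %d death probabilities outside [0,1]",
            int(((q[:-1] > 1) | (q[:-1] < 0)).sum()),
        )
        q[:-1] = np.clip(q[:-1], 0.0, 1.0)
    q[-1] = 1.0

    l = np.empty(k)
    l[0] = radix
    np.cumprod(1.0 - q[:-1], out=l[1:])
    l[1:] *= radix
    d = l * q
    L = np.empty(k)
    L[:-1] = n[:-1] * (l[:-1] - d[:-1]) + a[:-1] * d[:-1]
    L[-1] = l[-1] / m[-1]
    T = np.cumsum(L[::-1])[::-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        e = np.where(l > 0, T / l, 0.0)
    return x, n, m, a, q, l, d, L, T, e


def _le_sd_from_arrays(cols) -> tuple[float, float]:
    x, n, m, a, q, l, d, L, T, e = cols
    radix = l[0]
    e0 = T[0] / radix
    mean = np.sum(d * (x + a)) / radix
    closed = np.sum(d[:-1] * (x[:-1] + a[:-1] - mean) ** 2)
    open_term = d[-1] * ((x[-1] + a[-1] - mean) ** 2 + a[-1] ** 2)
    return float(e0), float(np.sqrt((closed + open_term) / radix))


def life_expectancy(lt: pd.DataFrame) -> float:
    """Life expectancy at birth: person-years above 0 per newborn."""
    return float(lt["T"].iloc[0] / lt["l"].iloc[0])


def lifespan_sd(lt: pd.DataFrame) -> float:
    """Standard deviation of the life-table distribution of age at death.

    Closed intervals are point masses d at x + a; the open interval adds
    its exponential within-interval variance (1/m)^2.
    """
    radix = float(lt["l"].iloc[0])
    x = lt["x"].to_numpy()
    a = lt["a"].to_numpy()
    d = lt["d"].to_numpy()
    # Mean age at death from the masses; equals x[0] + e0 identically
    # (so e0 itself for a ladder starting at birth).
    mean = float(np.sum(d * (x + a)) / radix)
    closed = np.sum(d[:-1] * (x[:-1] + a[:-1] - mean) ** 2)
    tail_mean_age = x[-1] + a[-1]  # a = 1/m in the open interval
    open_term = d[-1] * ((tail_mean_age - mean) ** 2 + a[-1] ** 2)
    return float(np.sqrt((closed + open_term) / radix))


@dataclass(frozen=True)
class GapResult:
    """A signed cross-country difference, reference minus comparator.

    With a reference country fixed, a positive gap means the reference has
    the larger value of the measure (longer LE, or greater LI).
    """

    measure: str  # "LE" or "LI"
    reference: float
    comparator: float

    @property
    def gap(self) -> float:
        return self.reference - self.comparator


def gap(measure: str, reference: float, comparator: float) -> GapResult:
    """Signed gap in LE or LI, oriented reference minus comparator."""
    if measure not in {"LE", "LI"}:
        raise ValueError(f"measure must be 'LE' or 'LI', got {measure!r}")
    if not (np.isfinite(reference) and np.isfinite(comparator)):
        raise ValueError("gap requires finite values")
    return GapResult(measure=measure, reference=float(reference), comparator=float(comparator))


MEASURES = {"LE": life_expectancy, "LI": lifespan_sd}


def measure_from_rates(measure: str, m_all_cause: np.ndarray, **lt_kwargs) -> float:
    """Evaluate LE or LI directly from an all-cause rate schedule.

    Equivalent to ``MEASURES[measure](build_lifetable(...))`` but skips
    the DataFrame wrapper; used by the decomposition, which evaluates the
    measures thousands of times along the path.
    """
    if measure not in MEASURES:
        raise ValueError(f"measure must be one of {sorted(MEASURES)}")
    e0, sd = _le_sd_from_arrays(_lifetable_arrays(m_all_cause, **lt_kwargs))
    return e0 if measure == "LE" else sd
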