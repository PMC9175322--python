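"""Canonical abridged age ladder.

All tables in this package live on the 19-group ladder used by the WHO
mortality database: [0,1), [1,5), [5,10), ..., [80,85), [85,+inf). The
terminal group is open-ended; its width is reported as ``OPEN``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Sentinel width for the open-ended terminal age group.
OPEN: float = float("inf")

#: Lower bounds of the canonical ladder (years).
LADDER_LOWER: tuple[int, ...] = (0, 1) + tuple(range(5, 90, 5))

#: Interval widths (years); the last is open.
LADDER_WIDTH: tuple[float, ...] = (1.0, 4.0) + (5.0,) * 16 + (OPEN,)

N_GROUPS: int = len(LADDER_LOWER)  # 19


@dataclass(frozen=True, order=True)
class AgeGroup:
    """One interval of the abridged ladder.

    Parameters
    ----------
    lower : int
        Lower bound in years.
    width : float
        Interval width in years; ``math.inf`` (``OPEN``) for the terminal
        85+ group.
    """

    lower: int
    width: float

    def __post_init__(self) -> None:
        if self.lower not in LADDER_LOWER:
            raise ValueError(
                f"age group lower bound {self.lower} not on the canonical "
                f"ladder {LADDER_LOWER}"
            )
        expected = LADDER_WIDTH[LADDER_LOWER.index(self.lower)]
        if self.width != expected:
            raise ValueError(
                f"age group [{self.lower}, ...) must have width {expected}, "
                f"got {self.width}"
            )

    @property
    def is_open(self) -> bool:
        return np.isinf(self.width)

    @property
    def midpoint(self) -> float:
        """Interval midpoint; by convention lower + 5 for the open group."""
        return self.lower + (5.0 if self.is_open else self.width / 2.0)

    def __str__(self) -> str:
        if self.is_open:
            return f"{self.lower}+"
        if self.width == 1:
            return str(self.lower)
        return f"{self.lower}-{self.lower + int(self.width) - 1}"


#: The full canonical ladder, in order.
LADDER: tuple[AgeGroup, ...] = tuple(
    AgeGroup(lo, w) for lo, w in zip(LADDER_LOWER, LADDER_WIDTH)
)


def group_for_lower(lower: int) -> AgeGroup:
    """Return the canonical group with the given lower bound."""
    try:
        return LADDER[LADDER_LOWER.index(lower)]
    except ValueError:
        raise ValueError(
            f"no canonical age group starts at {lower}; "
            f"valid lower bounds are {LADDER_LOWER}"
        ) from None


def validate_lower_bounds(lowers) -> None:
    """Raise ValueError if any value is not a canonical lower bound."""
    bad = sorted(set(lowers) - set(LADDER_LOWER))
    if bad:
        raise ValueError(f"unknown age-group lower bounds: {bad}")
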