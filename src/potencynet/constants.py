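"""Shared constants: the ordered potency categories and their score anchors.

Six broad potency categories are ordered by increasing developmental
potential, from fully differentiated cells to the totipotent zygote.
Throughout the package a category is represented either by its name or by
its integer *code* (1 = differentiated ... 6 = totipotent).
"""

from __future__ import annotations

import numpy as np

#: Broad potency categories in ascending order of developmental potential.
CATEGORIES: tuple[str, ...] = (
    "differentiated",
    "unipotent",
    "oligopotent",
    "multipotent",
    "pluripotent",
    "totipotent",
)

#: Number of potency categories (G).
N_CATEGORIES: int = len(CATEGORIES)

#: Ordered calibration vector t mapping category likelihoods to a potency
#: score in [0, 1]: 0.0 for differentiated up to 1.0 for totipotent.
T_VEC: np.ndarray = np.array([0.0, 0.2, 0.4, 0.6, 0.8, 1.0])

_NAME_TO_CODE = {name: i + 1 for i, name in enumerate(CATEGORIES)}


def category_code(name: str) -> int:
    """Return the 1-based integer code of a category name."""
    try:
        return _NAME_TO_CODE[name]
    except KeyError:
        raise ValueError(
            f"unknown potency category {name!r}; expected one of {CATEGORIES}"
        ) from None


def category_codes(names) -> np.ndarray:
    """Vectorized :func:`category_code`."""
    return np.array([category_code(n) for n in names], dtype=int)


def category_name(code: int) -> str:
    """Return the category name for a 1-based integer code."""
    if not 1 <= code <= N_CATEGORIES:
        raise ValueError(f"category code must be in 1..{N_CATEGORIES}, got {code}")
    return CATEGORIES[code - 1]
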