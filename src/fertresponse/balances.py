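"""Isometric log-ratio (ilr) balances for compositional data.

A balance scheme is a sequential binary partition (SBP) of the parts of a
composition.  Each contrast ``[denominator parts | numerator parts]`` maps to
one orthonormal log-ratio coordinate

    b_j = sqrt(r_j * s_j / (r_j + s_j)) * ln( g(numerator) / g(denominator) )

where ``r_j`` and ``s_j`` are the number of denominator and numerator parts
and ``g`` is the geometric mean.  A positive balance means the numerator
group dominates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BalanceScheme",
    "ilr_transform",
    "ilr_inverse",
    "impute_size_zeros",
    "TEXTURE_CARBON",
    "P_AL",
    "K_CA_MG",
    "SOIL_TYPE",
    "TUBER_SIZE",
]


class CompositionError(ValueError):
    """Raised for invalid compositional input (zeros, negatives, bad shapes)."""


def _parse_contrast(text: str) -> tuple[tuple[str, ...], tuple[str, ...]]:
    inner = text.strip().strip("[]")
    left, right = inner.split("|")
    denom = tuple(p.strip() for p in left.split(",") if p.strip())
    num = tuple(p.strip() for p in right.split(",") if p.strip())
    return denom, num


@dataclass(frozen=True)
class BalanceScheme:
    """A named sequential binary partition over ``parts``.

    Parameters
    ----------
    name : str
        Label used in feature-column names.
    parts : tuple of str
        Ordered part names; a D-part scheme carries D-1 contrasts.
    contrasts : tuple
        Ordered ``(denominator_parts, numerator_parts)`` pairs.
    """

    name: str
    parts: tuple[str, ...]
    contrasts: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]

    def __post_init__(self) -> None:
        d = len(self.parts)
        if len(set(self.parts)) != d:
            raise ValueError("duplicate part names")
        if len(self.contrasts) != d - 1:
            raise ValueError(
                f"scheme {self.name!r}: {d} parts require {d - 1} contrasts, "
                f"got {len(self.contrasts)}"
            )
        # Verify the contrasts form a sequential binary partition: each
        # contrast must split one currently-unsplit group into its two sides.
        groups = [frozenset(self.parts)]
        for denom, num in self.contrasts:
            dset, nset = frozenset(denom), frozenset(num)
            if dset & nset:
                raise ValueError(f"scheme {self.name!r}: overlapping contrast sides")
            whole = dset | nset
            if whole not in groups:
                raise ValueError(
                    f"scheme {self.name!r}: contrast {sorted(whole)} does not "
                    "split an existing group (not a sequential binary partition)"
                )
            groups.remove(whole)
            if len(dset) > 1:
                groups.append(dset)
            if len(nset) > 1:
                groups.append(nset)

    @classmethod
    def from_strings(cls, name: str, contrasts: Iterable[str]) -> "BalanceScheme":
        """Build a scheme from ``"[a, b | c]"``-style contrast strings.

        Part order is the order of first appearance in the contrast list.
        """
        parsed = tuple(_parse_contrast(c) for c in contrasts)
        parts: list[str] = []
        for denom, num in parsed:
            for p in (*denom, *num):
                if p not in parts:
                    parts.append(p)
        return cls(name=name, parts=tuple(parts), contrasts=parsed)

    @property
    def n_parts(self) -> int:
        return len(self.parts)

    def balance_names(self) -> list[str]:
        out = []
        for denom, num in self.contrasts:
            out.append(f"[{','.join(denom)}|{','.join(num)}]")
        return out

    def basis(self) -> np.ndarray:
        """Orthonormal contrast matrix, shape (D-1, D).

        Row j holds +sqrt(rs/(r+s))/s on numerator parts and
        -sqrt(rs/(r+s))/r on denominator parts.
        """
        idx = {p: i for i, p in enumerate(self.parts)}
        psi = np.zeros((len(self.contrasts), len(self.parts)))
        for j, (denom, num) in enumerate(self.contrasts):
            r, s = len(denom), len(num)
            coef = np.sqrt(r * s / (r + s))
            for p in num:
                psi[j, idx[p]] = coef / s
            for p in denom:
                psi[j, idx[p]] = -coef / r
        return psi


def _as_2d(x) -> tuple[np.ndarray, bool]:
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1:
        return arr[None, :], True
    if arr.ndim == 2:
        return arr, False
    raise CompositionError("composition array must be 1- or 2-dimensional")


def ilr_transform(composition, scheme: BalanceScheme) -> np.ndarray:
    """Map strictly positive compositions to ilr balance coordinates.

    Accepts a 1-D part vector or a 2-D (rows, parts) array ordered as
    ``scheme.parts``.  Scale invariant: ``ilr(k*x) == ilr(x)``.

    Raises
    ------
    CompositionError
        If any part is zero or negative (impute zeros first).
    """
    arr, squeeze = _as_2d(composition)
    if arr.shape[1] != scheme.n_parts:
        raise CompositionError(
            f"expected {scheme.n_parts} parts, got {arr.shape[1]}"
        )
    if not np.all(arr > 0):
        raise CompositionError(
            "all parts must be strictly positive; impute zeros first "
            "(see impute_size_zeros)"
        )
    balances = np.log(arr) @ scheme.basis().T
    return balances[0] if squeeze else balances


def ilr_inverse(balances, scheme: BalanceScheme) -> np.ndarray:
    """Recover the closed (unit-sum) composition from balance coordinates."""
    arr = np.asarray(balances, dtype=float)
    squeeze = arr.ndim == 1
    if squeeze:
        arr = arr[None, :]
    if arr.shape[1] != scheme.n_parts - 1:
        raise CompositionError(
            f"expected {scheme.n_parts - 1} balances, got {arr.shape[1]}"
        )
    clr = arr @ scheme.basis()
    comp = np.exp(clr - clr.max(axis=1, keepdims=True))
    comp /= comp.sum(axis=1, keepdims=True)
    return comp[0] if squeeze else comp


def impute_size_zeros(
    fractions,
    detection_limit: float = 0.65,
    replacement: float | None = None,
) -> np.ndarray:
    """Multiplicative simple replacement of zero parts in closed compositions.

    For each part carrying zeros, the replacement value is
    ``detection_limit`` times the smallest observed nonzero value of that
    part (or a fixed ``replacement`` when given).  Nonzero parts of an
    affected row are shrunk by the total imputed mass so rows re-close to 1.

    Parameters
    ----------
    fractions : array-like, shape (n, D)
        Rows closed to 1 (small tolerance accepted).
    detection_limit : float
        Fraction of the per-part minimum nonzero value used as replacement.
    replacement : float, optional
        Fixed replacement value overriding the data-driven detection limit.

    Returns
    -------
    ndarray with no zeros, each row summing to 1.
    """
    arr, squeeze = _as_2d(fractions)
    if not (0 < detection_limit < 1):
        raise ValueError("detection_limit must lie in (0, 1)")
    if np.any(arr < 0):
        raise CompositionError("negative parts are not a composition")
    if np.any(arr.sum(axis=1) <= 0):
        raise CompositionError("a row with all parts zero cannot be imputed")

    out = arr.copy()
    delta = np.full(arr.shape[1], np.nan)
    for j in range(arr.shape[1]):
        nz = arr[:, j][arr[:, j] > 0]
        if nz.size:
            delta[j] = detection_limit * nz.min()
    if replacement is not None:
        if not (0 < replacement < 1):
            raise ValueError("replacement must lie in (0, 1)")
        delta[:] = replacement
    for i in range(out.shape[0]):
        zeros = out[i] == 0
        if not zeros.any():
            continue
        if np.isnan(delta[zeros]).any():
            raise CompositionError(
                "cannot impute a part that is zero in every row"
            )
        imputed = delta[zeros].sum()
        out[i, ~zeros] *= 1.0 - imputed
        out[i, zeros] = delta[zeros]
    out /= out.sum(axis=1, keepdims=True)
    return out[0] if squeeze else out


# Balance schemes used throughout the pipeline, in
# [denominator parts | numerator parts] notation.
TEXTURE_CARBON = BalanceScheme.from_strings(
    "texture_carbon",
    ["[sand, silt, clay | carbon]", "[clay | sand, silt]", "[silt | sand]"],
)
P_AL = BalanceScheme.from_strings("p_al", ["[Fv | Al, P]", "[Al | P]"])
K_CA_MG = BalanceScheme.from_strings(
    "k_ca_mg", ["[Fv, Mg, Ca | K]", "[Fv | Mg, Ca]", "[Mg | Ca]"]
)
SOIL_TYPE = BalanceScheme.from_strings(
    "soil_type",
    ["[loamy_gleyed, sandy_gleyed | podzolized]", "[loamy_gleyed | sandy_gleyed]"],
)
TUBER_SIZE = BalanceScheme.from_strings("tuber_size", ["[M, S | L]", "[S | M]"])
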