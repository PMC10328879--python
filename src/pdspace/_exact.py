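"""Exact rational scalar helpers and small dense linear algebra over Fractions.

All identities in this package (column sums, ratio normalisation, flow
conservation, barycentric coordinates) are exact statements, so arithmetic is
carried out in :class:`fractions.Fraction` whenever the inputs permit it.
Float inputs are tolerated with an absolute comparison tolerance of
``DEFAULT_TOL``.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Sequence, Union

Number = Union[Fraction, int, float]

#: absolute tolerance used whenever a comparison involves floats
DEFAULT_TOL = 1e-9


def parse_number(text: str) -> Fraction:
    """Parse ``"p/q"`` or a decimal/scientific literal as an exact Fraction."""
    text = text.strip()
    if "/" in text:
        num, den = text.split("/", 1)
        return Fraction(int(num), int(den))
    return Fraction(text)


def format_number(value: Number) -> str:
    """Render a number compactly; Fractions as ``p/q`` (or an integer)."""
    if isinstance(value, Fraction):
        if value.denominator == 1:
            return str(value.numerator)
        return f"{value.numerator}/{value.denominator}"
    return repr(value)


def is_exact(value: Number) -> bool:
    return isinstance(value, (Fraction, int))


def all_exact(values) -> bool:
    return all(is_exact(v) for v in values)


def near(a: Number, b: Number, tol: float = DEFAULT_TOL) -> bool:
    """Equality, exact when both sides are rational, within ``tol`` otherwise."""
    if is_exact(a) and is_exact(b):
        return a == b
    return abs(a - b) <= tol


def as_float(value: Number) -> float:
    return float(value)


# ---------------------------------------------------------------------------
# Small exact linear algebra (Gaussian elimination over Fraction matrices).
# The systems involved are tiny (at most ~30 x ~12) but are solved thousands
# of times by the property suites, which rules out symbolic matrix libraries.
# ---------------------------------------------------------------------------


def exact_rank(rows: Sequence[Sequence[Fraction]]) -> int:
    """Rank of a matrix given as a list of rows of Fractions."""
    m = [list(map(Fraction, row)) for row in rows]
    if not m:
        return 0
    ncols = len(m[0])
    rank = 0
    col = 0
    for col in range(ncols):
        pivot = next((r for r in range(rank, len(m)) if m[r][col] != 0), None)
        if pivot is None:
            continue
        m[rank], m[pivot] = m[pivot], m[rank]
        pv = m[rank][col]
        m[rank] = [x / pv for x in m[rank]]
        for r in range(len(m)):
            if r != rank and m[r][col] != 0:
                factor = m[r][col]
                m[r] = [a - factor * b for a, b in zip(m[r], m[rank])]
        rank += 1
        if rank == len(m):
            break
    return rank


def exact_solve(a: Sequence[Sequence[Fraction]], b: Sequence[Fraction]):
    """Solve the square system ``a x = b`` exactly.

    Returns the solution vector, or ``None`` if ``a`` is singular.
    """
    n = len(a)
    aug = [list(map(Fraction, row)) + [Fraction(b[i])] for i, row in enumerate(a)]
    for col in range(n):
        pivot = next((r for r in range(col, n) if aug[r][col] != 0), None)
        if pivot is None:
            return None
        aug[col], aug[pivot] = aug[pivot], aug[col]
        pv = aug[col][col]
        aug[col] = [x / pv for x in aug[col]]
        for r in range(n):
            if r != col and aug[r][col] != 0:
                factor = aug[r][col]
                aug[r] = [x - factor * y for x, y in zip(aug[r], aug[col])]
    return [aug[r][n] for r in range(n)]


def exact_lstsq(a: Sequence[Sequence[Fraction]], b: Sequence[Fraction]):
    """Least-squares solution of the (tall) system ``a x = b`` via normal
    equations, exact over Fractions.

    Returns ``(x, residual_is_zero)`` where ``residual_is_zero`` reports
    whether ``a x == b`` holds exactly.  Raises ``ValueError`` when the
    columns of ``a`` are linearly dependent.
    """
    nrows = len(a)
    ncols = len(a[0]) if nrows else 0
    ata = [
        [sum(a[r][i] * a[r][j] for r in range(nrows)) for j in range(ncols)]
        for i in range(ncols)
    ]
    atb = [sum(a[r][i] * b[r] for r in range(nrows)) for i in range(ncols)]
    x = exact_solve(ata, atb)
    if x is None:
        raise ValueError("columns are linearly dependent; system is degenerate")
    residual_zero = all(
        sum(a[r][i] * x[i] for i in range(ncols)) == b[r] for r in range(nrows)
    )
    return x, residual_zero
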