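"""Cyclic S-matrices from the twin-prime difference-set construction.

An S-matrix of order N is a binary 0/1 sensing matrix satisfying

    S @ S.T == ((N + 1) / 4) * (I + J),        J = all-ones,

which admits the closed-form inverse  S^-1 = 2/(N+1) * (2 S.T - J).
When built from a twin-prime difference set (N = P*Q with Q = P + 2 both
prime) the matrix is cyclic: every row is a cyclic rotation of the first,
so both the forward projection b = S u and the inverse are cyclic
(de)correlations computable with FFTs in O(N log N), and measurement
vectors can be rearranged into a P x Q "projection space" in which image
translations reappear as translations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import fft, ifft

__all__ = [
    "CyclicSMatrix",
    "build_twin_prime",
    "closed_form_inverse",
    "project",
    "to_projection_space",
    "from_projection_space",
]

# dense materialization guard: above this order all algebra is matrix-free
DENSE_LIMIT = 10_000


def _is_prime(n: int) -> bool:
    if n < 2:
        return False
    if n < 4:
        return True
    if n % 2 == 0:
        return False
    f = 3
    while f * f <= n:
        if n % f == 0:
            return False
        f += 2
    return True


def _legendre(a: np.ndarray, p: int) -> np.ndarray:
    """Legendre symbol (a/p) for odd prime p, vectorized; 0 when p | a."""
    r = np.asarray(
        [pow(int(x) % p, (p - 1) // 2, p) for x in np.atleast_1d(a)], dtype=np.int64
    )
    r[r == p - 1] = -1
    return r


@dataclass(frozen=True)
class CyclicSMatrix:
    """Cyclic S-matrix stored as its first row plus the twin-prime factors.

    Row ``i`` equals ``first_row`` rotated right by ``i`` positions, i.e.
    ``S[i, j] = first_row[(j - i) % N]``.
    """

    first_row: np.ndarray
    P: int
    Q: int
    _fr_fft: np.ndarray = field(repr=False, compare=False, default=None)

    def __post_init__(self):
        fr = np.ascontiguousarray(np.asarray(self.first_row, dtype=np.int8))
        object.__setattr__(self, "first_row", fr)
        object.__setattr__(self, "_fr_fft", fft(fr.astype(np.float64)))
        if fr.size != self.P * self.Q:
            raise ValueError(
                f"first row length {fr.size} != P*Q = {self.P * self.Q}"
            )

    @property
    def N(self) -> int:
        return self.P * self.Q

    @property
    def row_weight(self) -> int:
        return int(self.first_row.sum())

    def row(self, i: int) -> np.ndarray:
        """Materialize row i (pattern i) as a length-N 0/1 vector."""
        return np.roll(self.first_row, i)

    def pattern_2d(self, i: int) -> np.ndarray:
        """Pattern i arranged on the P x Q image grid (row-major)."""
        return self.row(i).reshape(self.P, self.Q)

    def dense(self) -> np.ndarray:
        """Full N x N integer matrix; refused above DENSE_LIMIT."""
        if self.N > DENSE_LIMIT:
            raise ValueError(
                f"order {self.N} exceeds dense limit {DENSE_LIMIT}; "
                "use the matrix-free operations"
            )
        idx = (np.arange(self.N)[None, :] - np.arange(self.N)[:, None]) % self.N
        return self.first_row[idx].astype(np.int64)

    # -- matrix-free algebra -------------------------------------------------

    def matvec(self, u: np.ndarray) -> np.ndarray:
        """b = S u via circular correlation of the first row with u."""
        u = np.asarray(u, dtype=np.float64).ravel()
        if u.size != self.N:
            raise ValueError(f"vector length {u.size} != order {self.N}")
        return np.real(ifft(fft(u) * np.conj(self._fr_fft)))

    def rmatvec(self, b: np.ndarray) -> np.ndarray:
        """u = S.T b via circular convolution of the first row with b."""
        b = np.asarray(b, dtype=np.float64).ravel()
        if b.size != self.N:
            raise ValueError(f"vector length {b.size} != order {self.N}")
        return np.real(ifft(fft(b) * self._fr_fft))


def build_twin_prime(P: int, Q: int) -> CyclicSMatrix:
    """Construct the cyclic S-matrix of order N = P*Q for twin primes P, Q.

    The twin-prime difference set is

        D = {i : chi_P(i) * chi_Q(i) = 1}  U  {i : i = 0 (mod Q)},

    with chi the Legendre symbol; |D| = (N-1)/2. The S-matrix first row is
    the binary complement of D's incidence vector, giving row weight
    (N+1)/2 so that the closed-form inverse 2/(N+1) (2 S.T - J) holds.

    Raises
    ------
    ValueError
        If P or Q is not prime, or Q != P + 2.
    """
    if not _is_prime(P):
        raise ValueError(f"P = {P} is not prime")
    if not _is_prime(Q):
        raise ValueError(f"Q = {Q} is not prime")
    if Q != P + 2:
        raise ValueError(f"(P, Q) = ({P}, {Q}) are not twin primes: Q != P + 2")
    N = P * Q
    i = np.arange(N)
    chi = _legendre(i, P) * _legendre(i, Q)
    in_D = (chi == 1) | (i % Q == 0)
    first_row = (~in_D).astype(np.int8)
    S = CyclicSMatrix(first_row=first_row, P=P, Q=Q)
    # certification: the inverse formula is valid iff the row weight is right
    if S.row_weight != (N + 1) // 2:
        raise AssertionError(
            f"twin-prime construction failed: row weight {S.row_weight} "
            f"!= (N+1)/2 = {(N + 1) // 2}"
        )
    return S


def closed_form_inverse(S: CyclicSMatrix):
    """Return a function applying u = 2/(N+1) * (2 S.T - J) b matrix-free.

    S.T b is a cyclic convolution (FFT); J b is sum(b) broadcast.
    """
    N = S.N

    def apply(b: np.ndarray) -> np.ndarray:
        b = np.asarray(b, dtype=np.float64).ravel()
        if b.size != N:
            raise ValueError(f"measurement length {b.size} != order {N}")
        return (2.0 / (N + 1)) * (2.0 * S.rmatvec(b) - b.sum())

    return apply


def project(S: CyclicSMatrix, U: np.ndarray, method: str = "fft") -> np.ndarray:
    """Measure an image: b[i] = <row i of S, row-stacked u>.

    ``u[q + p*Q] = U[p, q]`` (row-major). ``method`` is "fft" (cyclic
    correlation, O(N log N)) or "dense" (explicit dot products, for
    cross-checking at small orders).
    """
    U = np.asarray(U, dtype=np.float64)
    if U.shape != (S.P, S.Q):
        raise ValueError(f"image shape {U.shape} != (P, Q) = ({S.P}, {S.Q})")
    u = U.ravel()
    if method == "fft":
        return S.matvec(u)
    if method == "dense":
        return S.dense().astype(np.float64) @ u
    raise ValueError(f"unknown method {method!r}")


def to_projection_space(b: np.ndarray, Q: int) -> np.ndarray:
    """Rearrange a measurement vector into projection space B[p,q] = b[q+p*Q].

    Accepts any length divisible by Q (full frames give P x Q; subset
    vectors of r whole pattern rows give r x Q).
    """
    b = np.asarray(b, dtype=np.float64).ravel()
    if b.size % Q != 0:
        raise ValueError(f"measurement length {b.size} not divisible by Q = {Q}")
    return b.reshape(-1, Q)


def from_projection_space(B: np.ndarray) -> np.ndarray:
    """Inverse of :func:`to_projection_space` (row-major flatten)."""
    return np.asarray(B, dtype=np.float64).ravel()
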