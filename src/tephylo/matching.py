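"""Two-sample Cramér-von Mises testing and greedy control-gene matching.

Control genes are matched to focal (piRNA-pathway) genes by the similarity
of their per-species omega distributions: every focal/candidate pair is
compared with a two-sample Cramér-von Mises test, and pairs are assigned
greedily by descending p-value, so that when two focal genes share a best
match the pair with the larger p-value wins and the loser takes its next
best candidate.

Because the per-gene samples are tiny (one omega per species), p-values are
computed by permutation of the pooled sample by default (seeded, with the
add-one correction); an asymptotic mode delegating to
:func:`scipy.stats.cramervonmises_2samp` is available for cross-checks.
The statistic is T = n*m/(n+m)^2 * sum over pooled points of
(Fa - Fb)^2, with empirical distribution functions evaluated at every pooled
sample point (tied values contribute once per copy, at their common EDF
height).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "MatchingError",
    "CvMResult",
    "MatchAssignment",
    "cvm_statistic",
    "cvm_test",
    "match_controls",
    "stable_seed",
]


class MatchingError(ValueError):
    """Invalid samples or an infeasible matching problem."""


@dataclass(frozen=True)
class CvMResult:
    statistic: float
    p: float
    method: str          # "permutation" | "asymptotic"
    n: int
    m: int


@dataclass(frozen=True)
class MatchAssignment:
    """Greedy matching result: (focal gene, control gene, p at assignment),
    in assignment (descending-p) order."""

    pairs: tuple

    def as_dict(self) -> dict[str, str]:
        return {g: c for g, c, _ in self.pairs}

    def __len__(self) -> int:
        return len(self.pairs)


def stable_seed(*parts) -> int:
    """A reproducible 31-bit seed derived by hashing the given parts.
    Independent of dict/iteration order of the caller's collections."""
    key = "\x1f".join(str(p) for p in parts)
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def cvm_statistic(a, b) -> float:
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    n, m = a.size, b.size
    z = np.sort(np.concatenate([a, b]))
    Fa = np.searchsorted(a, z, side="right") / n
    Fb = np.searchsorted(b, z, side="right") / m
    return float(n * m / (n + m) ** 2 * np.sum((Fa - Fb) ** 2))


def _perm_statistics(z: np.ndarray, n: int, n_perm: int, rng) -> np.ndarray:
    """Vectorized CvM statistics for n_perm random relabelings of the pooled
    sample z (first n labeled 'a')."""
    N = z.size
    m = N - n
    order = np.argsort(z, kind="stable")
    zs = z[order]
    # index of the last element of each tie group, so EDFs are evaluated at
    # the common height of tied values
    last = np.arange(N)
    for k in range(N - 2, -1, -1):
        if zs[k] == zs[k + 1]:
            last[k] = last[k + 1]
    pos_in_sorted = np.empty(N, dtype=np.intp)
    pos_in_sorted[order] = np.arange(N)
    # random subsets of size n for the 'a' labels
    u = rng.random((n_perm, N))
    idx = np.argsort(u, axis=1)[:, :n]
    member = np.zeros((n_perm, N), dtype=np.float64)
    rows = np.repeat(np.arange(n_perm), n)
    member[rows, pos_in_sorted[idx].ravel()] = 1.0
    cum_a = np.cumsum(member, axis=1)
    Fa = cum_a[:, last] / n
    Fb = (np.arange(1, N + 1)[last] - cum_a[:, last]) / m
    return n * m / (n + m) ** 2 * np.sum((Fa - Fb) ** 2, axis=1)


def cvm_test(
    a,
    b,
    n_perm: int = 9999,
    seed: int = 0,
    method: str = "permutation",
) -> CvMResult:
    """Two-sample Cramér-von Mises test.

    Permutation p-values carry the add-one correction
    p = (#{T_perm >= T_obs} + 1) / (n_perm + 1), so p is in (0, 1].
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise MatchingError("both samples need at least 2 values")
    t_obs = cvm_statistic(a, b)
    if method == "asymptotic":
        res = sps.cramervonmises_2samp(a, b, method="asymptotic")
        return CvMResult(
            statistic=t_obs, p=float(res.pvalue), method="asymptotic",
            n=a.size, m=b.size,
        )
    if method != "permutation":
        raise MatchingError(f"unknown method: {method!r}")
    if n_perm < 99:
        raise MatchingError("n_perm < 99 gives unstable permutation p-values")
    rng = np.random.default_rng(seed)
    z = np.concatenate([a, b])
    t_perm = _perm_statistics(z, a.size, n_perm, rng)
    hits = int(np.count_nonzero(t_perm >= t_obs - 1e-12))
    p = (hits + 1) / (n_perm + 1)
    return CvMResult(
        statistic=t_obs, p=float(p), method="permutation", n=a.size, m=b.size
    )


def match_controls(
    focal: dict,
    candidates: dict,
    n_perm: int = 9999,
    seed: int = 0,
    method: str = "permutation",
) -> MatchAssignment:
    """Greedily match each focal gene to a distinct candidate gene by
    Cramér-von Mises p-value.

    All pairwise p-values are computed once; then the unassigned
    (focal, candidate) pair with the maximum p is assigned repeatedly until
    every focal gene has a partner.  Exact p ties break lexicographically on
    (focal id, candidate id).  The result is injective both ways and
    independent of input iteration order.
    """
    focal = dict(focal)
    candidates = dict(candidates)
    if len(candidates) < len(focal):
        raise MatchingError(
            f"{len(candidates)} candidates cannot cover {len(focal)} focal genes"
        )
    shared = set(focal) & set(candidates)
    if shared:
        raise MatchingError(f"gene ids appear in both panels: {sorted(shared)}")
    pvals = []
    for g in sorted(focal):
        for c in sorted(candidates):
            res = cvm_test(
                focal[g], candidates[c],
                n_perm=n_perm, seed=stable_seed(seed, "cvm", g, c),
                method=method,
            )
            pvals.append((res.p, g, c))
    pvals.sort(key=lambda t: (-t[0], t[1], t[2]))
    assigned_f: set = set()
    assigned_c: set = set()
    pairs = []
    for p, g, c in pvals:
        if g in assigned_f or c in assigned_c:
            continue
        pairs.append((g, c, p))
        assigned_f.add(g)
        assigned_c.add(c)
        if len(assigned_f) == len(focal):
            break
    return MatchAssignment(pairs=tuple(pairs))
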