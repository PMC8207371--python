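"""Quadratic assignment procedure (QAP) for paired dyadic matrices.

Two association networks over the same animals are dependent data: the
dyads sharing a node are not independent, so an ordinary correlation
test across dyads is invalid. QAP builds the null distribution by
permuting *node labels* — one matrix's rows and columns are shuffled by
the same random relabeling — which preserves each matrix's full
topology and breaks only the node-to-node correspondence between the
two. That joint row+column shuffle is the defining move; cells are
never permuted independently.

Three similarity statistics are reported over the n(n-1)/2 unordered
off-diagonal dyads of two aligned binary matrices:

* **pearson** — the Pearson (phi) correlation of the two binary dyad
  vectors;
* **match** — the percentage of dyads in the same state (tie-tie or
  no-tie-no-tie) in both matrices;
* **jaccard** — of the dyads tied in at least one matrix, the
  percentage tied in both.

For binary data all three are monotone increasing functions of the
both-tied dyad count at fixed tie totals, and a node relabeling only
permutes each matrix's dyad multiset, so tie totals are
permutation-invariant: the three statistics share one permutation
p-value. Monte-Carlo p-values use the add-one (observed-included)
estimator p = (1 + #{perm >= obs}) / (1 + P), which can never be zero;
exhaustive mode enumerates all n! relabelings and reports the exact
proportion.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .networks import AssociationMatrix

_EPS = 1e-9


@dataclass(frozen=True)
class QAPResult:
    """Outcome of one QAP comparison.

    p-values lie in (0, 1]; they are ``None`` only when the chosen
    statistic is undefined (zero variance) on the observed data, in
    which case the test itself is undefined.
    """

    observed_pearson: float
    observed_match_pct: float
    observed_jaccard_pct: float
    statistic: str
    n_permutations: int
    p_value_greater: float | None
    p_value_two_sided: float | None
    seed: int | None
    mode: str  # "montecarlo" | "exhaustive"
    matrix_digest_a: str = ""
    matrix_digest_b: str = ""

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def _check_aligned_binary(a: AssociationMatrix, b: AssociationMatrix) -> None:
    if a.nodes != b.nodes:
        raise ValueError("matrices are not aligned: node lists differ")
    if not (a.is_binary() and b.is_binary()):
        raise ValueError("QAP similarity is defined on dichotomized matrices")
    if a.n_nodes < 3:
        raise ValueError("need at least 3 nodes")


def _stats_from_counts(n11: float, s_a: float, s_b: float, m: int) -> tuple[float, float, float]:
    """(pearson, match_pct, jaccard_pct) from the both-tied count.

    ``s_a``/``s_b`` are the tie counts of each dyad vector, ``m`` the
    number of dyads. Pearson is nan when either vector is constant;
    jaccard is nan when neither matrix has any tie.
    """
    var_a = s_a * (m - s_a)
    var_b = s_b * (m - s_b)
    if var_a == 0 or var_b == 0:
        pearson = math.nan
    else:
        pearson = (m * n11 - s_a * s_b) / math.sqrt(var_a * var_b)
    match = 100.0 * (m - s_a - s_b + 2 * n11) / m
    union = s_a + s_b - n11
    jaccard = math.nan if union == 0 else 100.0 * n11 / union
    return pearson, match, jaccard


def dyadic_similarity(
    a: AssociationMatrix, b: AssociationMatrix
) -> tuple[float, float, float]:
    """(pearson, match_pct, jaccard_pct) over the unordered dyads.

    Pearson is nan (flagged, not raised) when a dyad vector has zero
    variance; match and jaccard are still returned.
    """
    _check_aligned_binary(a, b)
    va = a.dyad_vector()
    vb = b.dyad_vector()
    m = va.size
    return _stats_from_counts(float(va @ vb), float(va.sum()), float(vb.sum()), m)


def _digest(m: AssociationMatrix) -> str:
    import hashlib

    h = hashlib.sha256()
    h.update(",".join(m.nodes).encode())
    h.update(np.ascontiguousarray(m.weights, dtype=np.int64).tobytes())
    return h.hexdigest()[:16]


def qap_test(
    a: AssociationMatrix,
    b: AssociationMatrix,
    n_permutations: int = 10_000,
    seed: int = 0,
    statistic: str = "pearson",
    mode: str = "montecarlo",
) -> QAPResult:
    """QAP permutation test of similarity between two aligned binary matrices.

    Each iteration draws one uniform node relabeling, applies it to
    ``b``'s rows and columns simultaneously, and recomputes the
    statistic. ``p_value_greater`` is the add-one upper-tail estimate;
    ``p_value_two_sided`` doubles the smaller tail (capped at 1). In
    ``exhaustive`` mode (n <= 8 nodes) all n! relabelings are
    enumerated and the p-values are exact proportions. Identical seeds
    give identical results.
    """
    _check_aligned_binary(a, b)
    if statistic not in ("pearson", "match"):
        raise ValueError("statistic must be 'pearson' or 'match'")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    n = a.n_nodes
    if mode == "exhaustive" and n > 8:
        raise ValueError("exhaustive mode is limited to n <= 8 nodes")
    if mode not in ("montecarlo", "exhaustive"):
        raise ValueError(f"unknown mode {mode!r}")

    wa = a.weights
    wb = b.weights
    m = n * (n - 1) // 2
    s_a = float(wa.sum()) / 2
    s_b = float(wb.sum()) / 2
    obs_n11 = float((wa * wb).sum()) / 2
    obs = _stats_from_counts(obs_n11, s_a, s_b, m)
    stat_index = 0 if statistic == "pearson" else 1
    obs_stat = obs[stat_index]

    digests = {"matrix_digest_a": _digest(a), "matrix_digest_b": _digest(b)}
    if math.isnan(obs_stat):
        return QAPResult(
            *obs, statistic, 0, None, None,
            seed if mode == "montecarlo" else None, mode, **digests,
        )

    # tie totals are invariant under node relabeling, so each permuted
    # statistic needs only the both-tied dyad count of the relabeled pair
    def perm_stat(p: np.ndarray) -> float:
        n11 = float((wa * wb[np.ix_(p, p)]).sum()) / 2
        return _stats_from_counts(n11, s_a, s_b, m)[stat_index]

    if mode == "exhaustive":
        stats = np.array(
            [perm_stat(np.array(p)) for p in itertools.permutations(range(n))]
        )
        total = stats.size
        ge = int((stats >= obs_stat - _EPS).sum())
        le = int((stats <= obs_stat + _EPS).sum())
        p_greater = ge / total
        p_two = min(1.0, 2.0 * min(ge, le) / total)
        n_used = total
        used_seed = None
    else:
        rng = np.random.default_rng(seed)
        stats = np.empty(n_permutations)
        for k in range(n_permutations):
            stats[k] = perm_stat(rng.permutation(n))
        ge = int((stats >= obs_stat - _EPS).sum())
        le = int((stats <= obs_stat + _EPS).sum())
        p_greater = (1 + ge) / (1 + n_permutations)
        p_lesser = (1 + le) / (1 + n_permutations)
        p_two = min(1.0, 2.0 * min(p_greater, p_lesser))
        n_used = n_permutations
        used_seed = seed

    return QAPResult(
        *obs, statistic, n_used, p_greater, p_two, used_seed, mode, **digests
    )
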