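"""Independent oracles used by the tests.

Everything here is deliberately coded from first principles (exhaustive
enumeration, direct formulas) and never calls the implementation paths it
checks.
"""

import itertools

import numpy as np

from barrierprio.aggregation import PairwiseMatrix


def random_orders(rng, items, n_ballots):
    """Random total orders (best first) over *items*."""
    items = list(items)
    return [list(rng.permutation(items)) for _ in range(n_ballots)]


def matrix_from_orders(items, orders, behaviour_id="x", attribute="difficulty"):
    """Pairwise-majority matrix built directly from best-first orders."""
    items = tuple(items)
    index = {b: i for i, b in enumerate(items)}
    n = len(items)
    prefer = np.zeros((n, n), dtype=int)
    for order in orders:
        for pos, a in enumerate(order):
            for b in order[pos + 1:]:
                prefer[index[a], index[b]] += 1
    return PairwiseMatrix(behaviour_id, attribute, items, prefer, len(orders))


def exhaustive_kemeny(matrix):
    """(best score, all optimal best-first orders) by full enumeration."""
    index = {b: i for i, b in enumerate(matrix.items)}
    best, optima = None, []
    for perm in itertools.permutations(matrix.items):
        score = 0
        for pos, a in enumerate(perm):
            for b in perm[pos + 1:]:
                score += int(matrix.prefer[index[b], index[a]])
        if best is None or score < best:
            best, optima = score, [perm]
        elif score == best:
            optima.append(perm)
    return best, optima


def kendall_tau(order, reference):
    """Pairwise-inversion distance between two total orders."""
    pos = {x: i for i, x in enumerate(order)}
    n = len(reference)
    return sum(
        1
        for i in range(n)
        for j in range(i + 1, n)
        if pos[reference[i]] > pos[reference[j]]
    )


def mallows_pmf(reference, dispersion):
    """Exact Mallows probabilities by enumerating all permutations."""
    weights = {
        perm: np.exp(-dispersion * kendall_tau(perm, list(reference)))
        for perm in itertools.permutations(reference)
    }
    z = sum(weights.values())
    return {perm: w / z for perm, w in weights.items()}


def linear_percentile(values, q):
    """Percentile with linear interpolation, coded from the formula."""
    xs = sorted(values)
    if len(xs) == 1:
        return float(xs[0])
    h = (len(xs) - 1) * q / 100.0
    lo = int(np.floor(h))
    hi = int(np.ceil(h))
    return float(xs[lo] + (h - lo) * (xs[hi] - xs[lo]))


def pareto_labels(points):
    """All-pairs desirability labels, independent second pass.

    *points* is a list of (barrier_id, influence, difficulty) triples.
    """

    def wdom(p, q):
        return (
            (p[1], p[2]) != (q[1], q[2])
            and p[1] >= q[1]
            and p[2] >= q[2]
        )

    labels = {}
    for p in points:
        if any(wdom(q, p) for q in points):
            labels[p[0]] = "least_desirable"
        elif all(
            (q[1], q[2]) == (p[1], p[2]) or wdom(p, q)
            for q in points
            if q is not p
        ):
            labels[p[0]] = "most_desirable"
        else:
            labels[p[0]] = "desirable"
    return labels
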