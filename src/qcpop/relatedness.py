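"""Pairwise relatedness: method-of-moments IBD, KING-robust kinship,
relationship classification, family assembly, and unrelated-set selection.

The IBD estimator inverts the conditional probabilities P(IBS = k | IBD = m)
implied by per-variant allele frequencies, yielding genome-wide proportions
(Z0, Z1, Z2) of sites sharing 0/1/2 alleles identical by descent and the
summary PI_HAT = Z1/2 + Z2.  Expected values sit at 0.5 for first-degree,
0.25 for second-degree, 0.125 for third-degree relatives, with consanguineous
compound relationships (e.g. triple second cousins, 0.09375) in between.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data import MISSING, GenotypeDataset

# classification thresholds
PI_HAT_DUPLICATE = 0.95
PI_HAT_FIRST_DEGREE = 0.375
PI_HAT_SECOND_DEGREE = 0.1875
PARENT_CHILD_Z0_MAX = 0.05
PARENT_CHILD_Z1_MIN = 0.5
KINSHIP_UNRELATED_CUTOFF = 0.05
# third-degree kinship band: standard half-open degree bins around 2^-4.5, 2^-3.5
THIRD_DEGREE_KINSHIP = (0.0442, 0.0884)


@dataclass
class IBDEstimate:
    """Method-of-moments IBD sharing for one sample pair."""

    i: str
    j: str
    z0: float
    z1: float
    z2: float
    pi_hat: float
    kinship: float = np.nan
    n_sites: int = 0
    raw: tuple = ()  # pre-clip (z0, z1, z2), kept for audit


def _ibs_expectations(p: np.ndarray):
    """Per-variant P(IBS=k | IBD=m) for allele frequency p (counted allele)."""
    q = 1.0 - p
    e = {}
    e[(0, 0)] = 2 * p**2 * q**2
    e[(1, 0)] = 4 * p**3 * q + 4 * p * q**3
    e[(2, 0)] = p**4 + q**4 + 4 * p**2 * q**2
    e[(1, 1)] = 2 * p**2 * q + 2 * p * q**2
    e[(2, 1)] = 1.0 - (2 * p**2 * q + 2 * p * q**2)
    e[(2, 2)] = np.ones_like(p)
    return e


def estimate_ibd(
    calls_i: np.ndarray,
    calls_j: np.ndarray,
    allele_freqs: np.ndarray,
    ids: tuple[str, str] = ("i", "j"),
    min_overlap: int = 1000,
    kinship: float = np.nan,
) -> IBDEstimate:
    """Method-of-moments (Z0, Z1, Z2, PI_HAT) for one pair of genotype vectors.

    Parameters
    ----------
    calls_i, calls_j
        int8 dosage vectors (0/1/2, -1 missing) over the same variants.
    allele_freqs
        Counted-allele frequencies in the analysis population (same order).
    min_overlap
        Minimum number of jointly non-missing autosomal sites.
    """
    gi = np.asarray(calls_i)
    gj = np.asarray(calls_j)
    p = np.asarray(allele_freqs, dtype=float)
    ok = (gi != MISSING) & (gj != MISSING) & np.isfinite(p) & (p > 0) & (p < 1)
    n = int(ok.sum())
    if n < min_overlap:
        raise ValueError(
            f"only {n} overlapping informative genotypes; need >= {min_overlap}"
        )
    gi, gj, p = gi[ok], gj[ok], p[ok]

    diff = np.abs(gi.astype(np.int16) - gj.astype(np.int16))
    het_i = gi == 1
    het_j = gj == 1
    ibs0 = (diff == 2) & ~het_i & ~het_j  # opposite homozygotes
    ibs2 = diff == 0
    n0 = float(ibs0.sum())
    n2 = float(ibs2.sum())
    n1 = float(n - n0 - n2)

    e = _ibs_expectations(p)
    s00 = e[(0, 0)].sum()
    z0 = n0 / s00 if s00 > 0 else 0.0
    s11 = e[(1, 1)].sum()
    z1 = (n1 - z0 * e[(1, 0)].sum()) / s11 if s11 > 0 else 0.0
    z2 = (n2 - z0 * e[(2, 0)].sum() - z1 * e[(2, 1)].sum()) / n
    raw = (z0, z1, z2)

    z = np.array([raw[0], raw[1], raw[2]], dtype=float)
    z = np.clip(z, 0.0, None)
    total = z.sum()
    if total > 0:
        z = z / total
    else:
        z = np.array([1.0, 0.0, 0.0])
    pi_hat = float(z[1] / 2.0 + z[2])
    return IBDEstimate(
        i=ids[0], j=ids[1], z0=float(z[0]), z1=float(z[1]), z2=float(z[2]),
        pi_hat=pi_hat, kinship=kinship, n_sites=n, raw=raw,
    )


def king_kinship(calls_i: np.ndarray, calls_j: np.ndarray) -> float:
    """KING-robust within-pair kinship from heterozygote concordance.

    phi = (N_het,het - 2 * N_opposite_hom) / (N_het(i) + N_het(j)), counted
    over jointly non-missing sites.  Duplicates give ~0.5, full siblings
    ~0.25; the estimator is robust to population allele-frequency structure.
    """
    gi = np.asarray(calls_i)
    gj = np.asarray(calls_j)
    ok = (gi != MISSING) & (gj != MISSING)
    gi, gj = gi[ok], gj[ok]
    het_i = gi == 1
    het_j = gj == 1
    n_het_i = int(het_i.sum())
    n_het_j = int(het_j.sum())
    if n_het_i + n_het_j == 0:
        return np.nan
    n_hethet = int((het_i & het_j).sum())
    n_opp = int(((np.abs(gi.astype(np.int16) - gj.astype(np.int16)) == 2)).sum())
    return (n_hethet - 2.0 * n_opp) / (n_het_i + n_het_j)


def pairwise_ibd_table(
    dataset: GenotypeDataset,
    allele_freqs: np.ndarray | None = None,
    pairs: Iterable[tuple[int, int]] | None = None,
    by_region: bool = False,
    min_overlap: int = 200,
) -> pd.DataFrame:
    """IBD + KING kinship for sample pairs (all pairs, or within-region only).

    Near relatives are assumed not to span recruitment regions, so the
    default biobank-scale scan is within-region; ``by_region=False`` scans
    every pair (sensible for small synthetic cohorts).
    """
    auto = dataset.autosomal_mask()
    ds = dataset.subset(variant_idx=auto) if not auto.all() else dataset
    if allele_freqs is None:
        allele_freqs = ds.allele_frequencies()
    else:
        allele_freqs = np.asarray(allele_freqs, dtype=float)[auto] if not auto.all() \
            else np.asarray(allele_freqs, dtype=float)
    ids = ds.samples["id"].to_numpy()
    if pairs is None:
        idx = np.arange(ds.n_samples)
        if by_region and "region" in ds.samples.columns:
            region = ds.samples["region"].to_numpy()
            pairs = [
                (i, j)
                for i, j in itertools.combinations(idx, 2)
                if region[i] == region[j]
            ]
        else:
            pairs = list(itertools.combinations(idx, 2))
    rows = []
    for i, j in pairs:
        kin = king_kinship(ds.calls[i], ds.calls[j])
        est = estimate_ibd(
            ds.calls[i], ds.calls[j], allele_freqs,
            ids=(ids[i], ids[j]), min_overlap=min_overlap, kinship=kin,
        )
        rows.append(
            (est.i, est.j, est.z0, est.z1, est.z2, est.pi_hat, est.kinship, est.n_sites)
        )
    return pd.DataFrame(
        rows, columns=["i", "j", "z0", "z1", "z2", "pi_hat", "kinship", "n_sites"]
    )


@dataclass
class RelationshipCall:
    pair: tuple[str, str]
    call: str
    parent: str | None = None
    evidence: dict = field(default_factory=dict)


def classify_relationship(
    est: IBDEstimate, age_i: float | None = None, age_j: float | None = None
) -> RelationshipCall:
    """Threshold-based relationship call from one IBD estimate.

    PI_HAT > 0.95 duplicate/MZ; > 0.375 first degree (parent-child when
    Z0 < 0.05 and Z1 > 0.5, the parent being the older of the pair, else
    full sibling); > 0.1875 second degree; kinship in the third-degree band
    third degree; otherwise unrelated.
    """
    ev = {
        "z0": est.z0, "z1": est.z1, "pi_hat": est.pi_hat, "kinship": est.kinship,
    }
    pair = (est.i, est.j)
    if est.pi_hat > PI_HAT_DUPLICATE:
        return RelationshipCall(pair, "duplicate_or_MZ", evidence=ev)
    if est.pi_hat > PI_HAT_FIRST_DEGREE:
        if est.z0 < PARENT_CHILD_Z0_MAX and est.z1 > PARENT_CHILD_Z1_MIN:
            parent = None
            if age_i is not None and age_j is not None:
                if age_i > age_j:
                    parent = est.i
                elif age_j > age_i:
                    parent = est.j
                else:
                    ev["direction"] = "unresolved_equal_ages"
            return RelationshipCall(pair, "parent_child", parent=parent, evidence=ev)
        return RelationshipCall(pair, "full_sibling", evidence=ev)
    if est.pi_hat > PI_HAT_SECOND_DEGREE:
        return RelationshipCall(pair, "second_degree", evidence=ev)
    lo, hi = THIRD_DEGREE_KINSHIP
    if np.isfinite(est.kinship) and lo < est.kinship <= hi:
        return RelationshipCall(pair, "third_degree", evidence=ev)
    return RelationshipCall(pair, "unrelated", evidence=ev)


def expected_ibd(connections: Sequence) -> tuple[float, float, float, float]:
    """Analytic expected (Z0, Z1, Z2, PI_HAT) for a pedigree relationship.

    ``connections`` is a list of independent pedigree connections, each either

    * an int ``m`` — a connection of ``m`` meioses through a *couple* of
      common ancestors (siblings m=2, first cousins m=4, second cousins m=6);
    * a tuple ``(m, a)`` — ``m`` meioses through ``a`` common ancestor(s)
      (half siblings: ``(2, 1)``); or
    * a tuple ``(m, a, side)`` with ``side`` in {"maternal", "paternal"}
      to control through which parental gamete the connection runs.

    Each connection contributes kinship ``a * 2**-(m + 1)``; the expected
    IBD-sharing proportion is exactly PI_HAT = 2 * sum(kinship) by linearity.
    Z components assume connections are independent, each parental gamete
    carrying at most the union of its side's connections.  Special cases:
    ``["self"]`` for duplicates/MZ (1, analytically (0,0,1)), ``["parent"]``
    for parent-offspring ((0,1,0)).
    """
    if not isinstance(connections, (list, tuple)):
        raise TypeError("relationship descriptor must be a sequence of connections")
    if len(connections) == 0:
        return (1.0, 0.0, 0.0, 0.0)
    if list(connections) == ["self"]:
        return (0.0, 0.0, 1.0, 1.0)
    if list(connections) == ["parent"]:
        return (0.0, 1.0, 0.0, 0.5)

    kin_total = 0.0
    # per-side probability that the gametes passed by that parent pair are IBD;
    # at a single locus, IBD through distinct ancestor couples is mutually
    # exclusive (one ancestral lineage per allele), so probabilities add.
    shared = {"maternal": 0.0, "paternal": 0.0}
    alternate = itertools.cycle(["maternal", "paternal"])
    for conn in connections:
        if isinstance(conn, int):
            m, a, side = conn, 2, next(alternate)
        elif isinstance(conn, tuple) and len(conn) == 2:
            (m, a), side = conn, next(alternate)
        elif isinstance(conn, tuple) and len(conn) == 3:
            m, a, side = conn
        else:
            raise ValueError(f"malformed connection descriptor: {conn!r}")
        if m < 1 or a not in (1, 2):
            raise ValueError(f"malformed connection descriptor: {conn!r}")
        phi = a * 2.0 ** -(m + 1)
        kin_total += phi
        r = a * 2.0 ** -(m - 1)  # = 4 * phi = P(IBD through this connection)
        if m == 2 and a == 2:
            # full-sibling couple connection spans both parental gametes
            shared["maternal"] += 0.5
            shared["paternal"] += 0.5
        else:
            shared[side] += r
    pm = min(1.0, shared["maternal"])
    pp = min(1.0, shared["paternal"])
    z2 = pm * pp
    z1 = pm * (1 - pp) + pp * (1 - pm)
    z0 = (1 - pm) * (1 - pp)
    pi_hat = 2.0 * kin_total
    return (z0, z1, z2, pi_hat)


@dataclass
class FamilyGraph:
    """First/second-degree relationship graph with derived structures."""

    components: list            # list of sets of sample ids (first-degree)
    sibling_groups: list        # list of sets (cliques of full_sibling edges)
    parent_child: list          # list of (parent, child) or (i, j, None) if undirected
    trios: list                 # list of (child, parent_a, parent_b)
    review: list                # flagged inconsistencies (e.g. 3/4-sib candidates)


def build_families(calls: Sequence[RelationshipCall], manifest: pd.DataFrame | None = None) -> FamilyGraph:
    """Assemble sibling groups, parent-child arcs and trios from pair calls.

    Sibling groups are maximal connected sets of full_sibling edges; a group
    that is not a clique (some internal pair not called full sibling) is
    flagged for review — the signature of three-quarter siblings and similar
    intermediate-kinship structures.  A trio is a child with parent arcs from
    two samples that are not themselves first-degree relatives.
    """
    first_degree = {"parent_child", "full_sibling"}
    adj: dict[str, set[str]] = {}
    sib_adj: dict[str, set[str]] = {}
    parent_arcs: list[tuple[str, str]] = []
    undirected_pc: list[tuple[str, str]] = []
    called = {}
    for c in calls:
        i, j = c.pair
        called[frozenset((i, j))] = c.call
        if c.call in first_degree:
            adj.setdefault(i, set()).add(j)
            adj.setdefault(j, set()).add(i)
        if c.call == "full_sibling":
            sib_adj.setdefault(i, set()).add(j)
            sib_adj.setdefault(j, set()).add(i)
        if c.call == "parent_child":
            if c.parent is not None:
                child = j if c.parent == i else i
                parent_arcs.append((c.parent, child))
            else:
                undirected_pc.append((i, j))

    # cycle check on directed parent arcs
    children: dict[str, list[str]] = {}
    for p, ch in parent_arcs:
        children.setdefault(p, []).append(ch)
    state: dict[str, int] = {}

    def _dfs(node, stack):
        state[node] = 1
        stack.append(node)
        for nxt in children.get(node, []):
            if state.get(nxt, 0) == 1:
                cycle = stack[stack.index(nxt):] + [nxt]
                raise ValueError(f"parent-child cycle: {' -> '.join(cycle)}")
            if state.get(nxt, 0) == 0:
                _dfs(nxt, stack)
        stack.pop()
        state[node] = 2

    for node in list(children):
        if state.get(node, 0) == 0:
            _dfs(node, [])

    # connected components over first-degree edges
    seen: set[str] = set()
    components = []
    for start in adj:
        if start in seen:
            continue
        comp = set()
        stack = [start]
        while stack:
            node = stack.pop()
            if node in comp:
                continue
            comp.add(node)
            stack.extend(adj.get(node, ()) - comp)
        seen |= comp
        components.append(comp)

    # sibling groups = connected components of sibling edges; flag non-cliques
    review = []
    sib_groups = []
    sseen: set[str] = set()
    for start in sib_adj:
        if start in sseen:
            continue
        grp = set()
        stack = [start]
        while stack:
            node = stack.pop()
            if node in grp:
                continue
            grp.add(node)
            stack.extend(sib_adj.get(node, ()) - grp)
        sseen |= grp
        sib_groups.append(grp)
        for a, b in itertools.combinations(sorted(grp), 2):
            if called.get(frozenset((a, b))) != "full_sibling":
                review.append(
                    {"group": sorted(grp), "pair": (a, b),
                     "reason": "sibling_group_not_clique"}
                )

    # trios: child with two parents whose own pair is not first degree
    parents_of: dict[str, list[str]] = {}
    for p, ch in parent_arcs:
        parents_of.setdefault(ch, []).append(p)
    trios = []
    for ch, ps in parents_of.items():
        for pa, pb in itertools.combinations(sorted(set(ps)), 2):
            if called.get(frozenset((pa, pb))) not in first_degree:
                trios.append((ch, pa, pb))

    return FamilyGraph(
        components=components,
        sibling_groups=sib_groups,
        parent_child=parent_arcs + [(i, j) for i, j in undirected_pc],
        trios=trios,
        review=review,
    )


def greedy_unrelated_set(
    kinship: pd.DataFrame,
    cutoff: float = KINSHIP_UNRELATED_CUTOFF,
    all_ids: Sequence[str] | None = None,
    call_rates: dict | None = None,
) -> list[str]:
    """Greedy maximal unrelated set under a kinship cutoff.

    Iteratively drops the sample in the most above-cutoff pairs (ties broken
    by lower call rate, then lexicographic id) until no pair exceeds the
    cutoff.  ``kinship`` needs columns i, j, kinship.
    """
    edges = kinship.loc[kinship["kinship"] > cutoff, ["i", "j"]]
    adj: dict[str, set[str]] = {}
    nodes = set(all_ids) if all_ids is not None else set()
    nodes |= set(kinship["i"]) | set(kinship["j"])
    for i, j in edges.itertuples(index=False):
        adj.setdefault(i, set()).add(j)
        adj.setdefault(j, set()).add(i)
    removed = set()
    while True:
        degrees = {
            node: len(nbrs - removed)
            for node, nbrs in adj.items()
            if node not in removed
        }
        degrees = {k: v for k, v in degrees.items() if v > 0}
        if not degrees:
            break
        maxdeg = max(degrees.values())
        cands = [k for k, v in degrees.items() if v == maxdeg]
        if call_rates:
            cands.sort(key=lambda s: (call_rates.get(s, 1.0), s))
        else:
            cands.sort()
        removed.add(cands[0])
    return sorted(nodes - removed)
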