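"""FPC-style contig assembly from digitized fingerprints.

Pipeline stages mirror stringent physical-map practice: single-linkage
clustering at a stringent Sulston cutoff, consensus-band (CB) coordinate
layout, detection of questionable (Q) clones and DQer-style breakup of
suspect contigs at stepped-up stringency, and relaxed Ends-to-Ends /
Singles-to-Ends / evidence-supported merging.

Layout replaces FPC's simulated-annealing CB map with a deterministic
two-step procedure: clones in a contig are ordered by spectral seriation
(Fiedler vector of the match-count similarity Laplacian), then offsets are
propagated over a maximum-weight spanning tree of the overlap graph with
the edge offset estimate ``n_i - m_ij`` CB units applied signed along the
seriation order.  This is an approximation of FPC adequate for
coordinate-level uses (MTP spacing, marker placement).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import networkx as nx

from .fingerprint import (
    Fingerprint,
    ScoreParams,
    match_bands,
    sulston_log10,
    _log10_binomial_tail,
)

__all__ = [
    "ContigMember",
    "Contig",
    "PhysicalMap",
    "ScoreCache",
    "build_contigs",
    "layout_contig",
    "dqer",
    "relaxed_merge",
    "contig_summary",
]


@dataclass(frozen=True)
class ContigMember:
    clone_id: str
    left_cb: int
    right_cb: int
    q_flag: bool = False

    @property
    def span_cb(self) -> int:
        return self.right_cb - self.left_cb


@dataclass
class Contig:
    contig_id: str
    members: list[ContigMember]
    built_log10: float  # log10 Sulston cutoff the contig is connected at

    @property
    def clone_ids(self) -> list[str]:
        return [m.clone_id for m in self.members]

    @property
    def length_cb(self) -> int:
        if not self.members:
            return 0
        return max(m.right_cb for m in self.members) - min(
            m.left_cb for m in self.members
        )

    @property
    def q_fraction(self) -> float:
        if not self.members:
            return 0.0
        return sum(m.q_flag for m in self.members) / len(self.members)


@dataclass
class PhysicalMap:
    contigs: dict[str, Contig]
    singletons: list[str]
    params: ScoreParams
    log: list[str] = field(default_factory=list)

    @property
    def n_clones(self) -> int:
        return sum(len(c.members) for c in self.contigs.values()) + len(
            self.singletons
        )

    def all_clone_ids(self) -> set[str]:
        ids = set(self.singletons)
        for c in self.contigs.values():
            ids.update(c.clone_ids)
        return ids

    def contig_of(self) -> dict[str, str]:
        return {
            cid: ctg.contig_id
            for ctg in self.contigs.values()
            for cid in ctg.clone_ids
        }


class ScoreCache:
    """Lazy pairwise band-match counts and Sulston scores over a clone set,
    with a cheap upper-bound prefilter that skips the exact greedy matching
    for pairs that cannot reach the working cutoff."""

    def __init__(self, fingerprints: Sequence[Fingerprint], params: ScoreParams):
        self.params = params
        self.fps: dict[str, Fingerprint] = {}
        self.arrays: dict[str, np.ndarray] = {}
        for fp in fingerprints:
            if fp.clone_id in self.fps:
                raise ValueError(f"duplicate clone id {fp.clone_id}")
            self.fps[fp.clone_id] = fp
            self.arrays[fp.clone_id] = np.asarray(fp.bands, dtype=np.int64)
        self._m: dict[tuple[str, str], int] = {}
        self._window = (2 * params.tolerance + 1) / params.gellen

    def n_bands(self, cid: str) -> int:
        return self.arrays[cid].size

    def _key(self, a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def matched(self, a: str, b: str) -> int:
        key = self._key(a, b)
        m = self._m.get(key)
        if m is None:
            m = match_bands(self.arrays[a], self.arrays[b], self.params.tolerance)
            self._m[key] = m
        return m

    def upper_bound_matched(self, a: str, b: str) -> int:
        """Count of bands of the smaller list with any band of the larger
        within tolerance; an upper bound on the greedy matched count."""
        x, y = self.arrays[a], self.arrays[b]
        if x.size > y.size:
            x, y = y, x
        if x.size == 0:
            return 0
        t = self.params.tolerance
        idx = np.searchsorted(y, x)
        right_ok = (idx < y.size) & (np.take(y, np.minimum(idx, y.size - 1)) - x <= t)
        left_ok = (idx > 0) & (x - np.take(y, np.maximum(idx - 1, 0)) <= t)
        return int(np.count_nonzero(right_ok | left_ok))

    def log10_score(self, a: str, b: str) -> float:
        m = self.matched(a, b)
        return sulston_log10(self.n_bands(a), self.n_bands(b), m, self.params)

    def log10_upper_evidence(self, a: str, b: str) -> float:
        """Lower bound on the log10 score (optimistic), from the matched
        upper bound; if this exceeds a threshold the pair cannot pass it."""
        na, nb = self.n_bands(a), self.n_bands(b)
        n_low, n_high = min(na, nb), max(na, nb)
        if n_low == 0:
            return 0.0
        p = -np.expm1(n_high * np.log1p(-self._window))
        return _log10_binomial_tail(n_low, p, self.upper_bound_matched(a, b))

    def edges(self, clone_ids: Sequence[str], max_log10: float):
        """All pairs among ``clone_ids`` with log10 score <= max_log10,
        as (log10_score, a, b) sorted best (most negative) first."""
        ids = sorted(clone_ids)
        out = []
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                if self.log10_upper_evidence(a, b) > max_log10:
                    continue
                s = self.log10_score(a, b)
                if s <= max_log10:
                    out.append((s, a, b))
        out.sort()
        return out


def build_contigs(
    fingerprints: Sequence[Fingerprint],
    params: ScoreParams,
    cache: ScoreCache | None = None,
) -> PhysicalMap:
    """Single-linkage clustering at the Sulston cutoff: contigs are the
    connected components of the graph of pairs scoring at or below
    ``params.cutoff``; singleton components become singletons.  Contigs are
    laid out in CB coordinates on construction."""
    if cache is None:
        cache = ScoreCache(fingerprints, params)
    ids = sorted(fp.clone_id for fp in fingerprints)
    if not ids:
        return PhysicalMap({}, [], params, ["empty input"])
    max_log10 = params.log10_cutoff
    g = nx.Graph()
    g.add_nodes_from(ids)
    for s, a, b in cache.edges(ids, max_log10):
        g.add_edge(a, b, log10=s)
    contigs: dict[str, Contig] = {}
    singletons: list[str] = []
    comps = sorted(nx.connected_components(g), key=lambda c: min(c))
    k = 0
    for comp in comps:
        if len(comp) == 1:
            singletons.extend(comp)
            continue
        k += 1
        cid = f"ctg{k}"
        members = layout_contig(sorted(comp), cache, max_log10)
        contigs[cid] = Contig(cid, members, max_log10)
    singletons.sort()
    return PhysicalMap(
        contigs,
        singletons,
        params,
        [f"build at 1e{max_log10:.0f}: {len(contigs)} contigs, "
         f"{len(singletons)} singletons"],
    )


def layout_contig(
    clone_ids: Sequence[str],
    cache: ScoreCache,
    max_log10: float,
) -> list[ContigMember]:
    """Assign CB coordinates to the clones of one contig.

    Order comes from spectral seriation of the match-count similarity
    matrix; offsets are propagated over a maximum-weight spanning tree
    (weight = matched bands), each tree edge contributing ``n_i - m_ij``
    CB units in the direction given by the seriation.  Coordinates are
    normalized to min 0; a clone's span equals its band count.
    """
    ids = sorted(clone_ids)
    if not ids:
        return []
    if len(ids) == 1:
        cid = ids[0]
        return [ContigMember(cid, 0, max(1, cache.n_bands(cid)))]
    edges = cache.edges(ids, max_log10)
    g = nx.Graph()
    g.add_nodes_from(ids)
    for s, a, b in edges:
        g.add_edge(a, b, weight=cache.matched(a, b), log10=s)
    if not nx.is_connected(g):
        raise ValueError("contig is not connected at the layout cutoff")

    # spectral seriation: Fiedler vector of L = D - A, A_ij = matched bands
    index = {cid: i for i, cid in enumerate(ids)}
    n = len(ids)
    A = np.zeros((n, n))
    for a, b, data in g.edges(data=True):
        A[index[a], index[b]] = A[index[b], index[a]] = data["weight"]
    L = np.diag(A.sum(axis=1)) - A
    vals, vecs = np.linalg.eigh(L)
    fiedler = vecs[:, 1]
    order = sorted(range(n), key=lambda i: (fiedler[i], ids[i]))
    if ids[order[0]] > ids[order[-1]]:
        order = order[::-1]
    rank = {ids[i]: r for r, i in enumerate(order)}

    mst = nx.maximum_spanning_tree(g, weight="weight")
    root = ids[order[0]]
    offset = {root: 0}
    for u, v in nx.bfs_edges(mst, root):
        m = cache.matched(u, v)
        if rank[v] >= rank[u]:
            offset[v] = offset[u] + (cache.n_bands(u) - m)
        else:
            offset[v] = offset[u] - (cache.n_bands(v) - m)
    base = min(offset.values())
    members = [
        ContigMember(
            cid, offset[cid] - base, offset[cid] - base + max(1, cache.n_bands(cid))
        )
        for cid in ids
    ]
    members.sort(key=lambda mb: (mb.left_cb, mb.clone_id))
    return members


def _q_flags(
    contig: Contig, cache: ScoreCache, q_band_fraction: float = 0.5
) -> list[ContigMember]:
    """Flag members whose bands poorly match the contig's pooled band
    consensus: a clone is questionable when more than ``q_band_fraction``
    of its bands have no pooled band (from the other members) within
    tolerance."""
    t = cache.params.tolerance
    ids = contig.clone_ids
    all_bands = {cid: cache.arrays[cid] for cid in ids}
    out = []
    for mb in contig.members:
        own = all_bands[mb.clone_id]
        others = [all_bands[c] for c in ids if c != mb.clone_id]
        if not others or own.size == 0:
            out.append(replace(mb, q_flag=False))
            continue
        pool = np.sort(np.concatenate(others))
        idx = np.searchsorted(pool, own)
        right_ok = (idx < pool.size) & (
            np.take(pool, np.minimum(idx, pool.size - 1)) - own <= t
        )
        left_ok = (idx > 0) & (own - np.take(pool, np.maximum(idx - 1, 0)) <= t)
        unmatched = own.size - int(np.count_nonzero(right_ok | left_ok))
        out.append(replace(mb, q_flag=unmatched > q_band_fraction * own.size))
    return out


def dqer(
    pmap: PhysicalMap,
    cache: ScoreCache,
    q_threshold: float = 0.10,
    max_steps: int = 3,
    step_factor: float = 1e-10,
) -> PhysicalMap:
    """Break up contigs with too many questionable clones.

    Each contig's members are Q-flagged against the pooled band consensus;
    a contig whose Q fraction exceeds ``q_threshold`` is re-clustered at a
    stringency increased by ``step_factor`` per step (up to ``max_steps``),
    stopping as soon as every resulting piece is below the threshold.
    Clone count is conserved; pieces of size one become singletons.
    """
    new_contigs: dict[str, Contig] = {}
    singletons = list(pmap.singletons)
    log = list(pmap.log)
    counter = 0

    def fresh_id() -> str:
        nonlocal counter
        counter += 1
        return f"ctg{counter}"

    for cid in sorted(pmap.contigs):
        contig = pmap.contigs[cid]
        contig = Contig(contig.contig_id, _q_flags(contig, cache), contig.built_log10)
        if contig.q_fraction <= q_threshold:
            new_contigs[fresh_id()] = Contig(
                None, contig.members, contig.built_log10
            )
            continue
        pieces = [contig]
        step = 0
        while step < max_steps and any(
            p.q_fraction > q_threshold and len(p.members) > 1 for p in pieces
        ):
            step += 1
            cut = contig.built_log10 + step * np.log10(step_factor)
            next_pieces: list[Contig] = []
            for p in pieces:
                if p.q_fraction <= q_threshold or len(p.members) == 1:
                    next_pieces.append(p)
                    continue
                ids = p.clone_ids
                g = nx.Graph()
                g.add_nodes_from(ids)
                for s, a, b in cache.edges(ids, cut):
                    g.add_edge(a, b)
                for comp in sorted(nx.connected_components(g), key=min):
                    if len(comp) == 1:
                        (only,) = comp
                        next_pieces.append(
                            Contig(
                                None,
                                [ContigMember(only, 0, max(1, cache.n_bands(only)))],
                                cut,
                            )
                        )
                    else:
                        members = layout_contig(sorted(comp), cache, cut)
                        sub = Contig(None, members, cut)
                        sub = Contig(None, _q_flags(sub, cache), cut)
                        next_pieces.append(sub)
            pieces = next_pieces
        broke = len(pieces) > 1
        for p in pieces:
            if len(p.members) == 1 and broke:
                singletons.append(p.members[0].clone_id)
            else:
                new_contigs[fresh_id()] = p
        if broke:
            log.append(
                f"DQer: {cid} (Q={contig.q_fraction:.2f}) -> {len(pieces)} pieces"
            )

    relabel = {}
    for k, key in enumerate(sorted(new_contigs, key=lambda c: int(c[3:])), 1):
        ctg = new_contigs[key]
        relabel[f"ctg{k}"] = Contig(f"ctg{k}", ctg.members, ctg.built_log10)
    return PhysicalMap(relabel, sorted(singletons), pmap.params, log)


def _end_clones(contig: Contig, end_window_cb: int) -> list[str]:
    if not contig.members:
        return []
    lo = min(m.left_cb for m in contig.members)
    hi = max(m.right_cb for m in contig.members)
    out = [
        m.clone_id
        for m in contig.members
        if m.left_cb < lo + end_window_cb or m.right_cb > hi - end_window_cb
    ]
    return out


def _median_span(pmap: PhysicalMap) -> int:
    spans = [m.span_cb for c in pmap.contigs.values() for m in c.members]
    if not spans:
        return 120
    return int(np.median(spans))


def relaxed_merge(
    pmap: PhysicalMap,
    cache: ScoreCache,
    cutoff: float,
    mode: str,
    end_window_cb: int | None = None,
    evidence: Mapping[str, Sequence[tuple[str, float]]] | None = None,
    cm_window: float = 10.0,
    floor: float = 1e-25,
) -> PhysicalMap:
    """Relaxed-stringency refinement of a laid-out map.

    ``ends_to_ends`` joins two contigs when a pair of their end clones
    (clones within ``end_window_cb`` of a contig extremity; default one
    median clone span) scores at or below ``cutoff``.  ``singles_to_ends``
    attaches singletons to contig ends the same way.  ``evidence`` mode is
    ends-to-ends allowed down to ``floor`` but only between contigs
    carrying genetic markers of the same linkage group within ``cm_window``
    centimorgans.  Merges apply best score first; merged contigs are
    re-laid out at the relaxed cutoff.
    """
    if mode not in ("ends_to_ends", "singles_to_ends", "evidence"):
        raise ValueError(f"unknown merge mode {mode!r}")
    if mode == "evidence" and evidence is None:
        raise ValueError("evidence mode requires a contig marker table")
    if end_window_cb is None:
        end_window_cb = _median_span(pmap)
    working_cutoff = floor if mode == "evidence" else cutoff
    max_log10 = float(np.log10(working_cutoff))
    log = list(pmap.log)

    if mode == "singles_to_ends":
        assignment: dict[str, str] = {}
        candidates = []
        ends = {
            cid: _end_clones(c, end_window_cb) for cid, c in pmap.contigs.items()
        }
        for s in sorted(pmap.singletons):
            for cid in sorted(pmap.contigs):
                best = None
                for e in ends[cid]:
                    if cache.log10_upper_evidence(s, e) > max_log10:
                        continue
                    v = cache.log10_score(s, e)
                    if v <= max_log10 and (best is None or v < best):
                        best = v
                if best is not None:
                    candidates.append((best, s, cid))
        candidates.sort()
        for _, s, cid in candidates:
            if s not in assignment:
                assignment[s] = cid
        new_contigs = {}
        for cid in sorted(pmap.contigs):
            ids = list(pmap.contigs[cid].clone_ids) + [
                s for s, c in assignment.items() if c == cid
            ]
            if len(ids) > len(pmap.contigs[cid].members):
                members = layout_contig(sorted(ids), cache, max_log10)
                new_contigs[cid] = Contig(cid, members, max_log10)
            else:
                new_contigs[cid] = pmap.contigs[cid]
        singles = sorted(set(pmap.singletons) - set(assignment))
        if assignment:
            log.append(
                f"singles_to_ends at 1e{max_log10:.0f}: attached {len(assignment)}"
            )
        return PhysicalMap(new_contigs, singles, pmap.params, log)

    # contig-contig merging (ends_to_ends / evidence)
    ends = {cid: _end_clones(c, end_window_cb) for cid, c in pmap.contigs.items()}
    cids = sorted(pmap.contigs)
    candidates = []
    for i, c1 in enumerate(cids):
        for c2 in cids[i + 1 :]:
            if mode == "evidence" and not _shares_linkage(
                evidence.get(c1, ()), evidence.get(c2, ()), cm_window
            ):
                continue
            best = None
            for e1 in ends[c1]:
                for e2 in ends[c2]:
                    if cache.log10_upper_evidence(e1, e2) > max_log10:
                        continue
                    v = cache.log10_score(e1, e2)
                    if v <= max_log10 and (best is None or v < best):
                        best = v
            if best is not None:
                candidates.append((best, c1, c2))
    candidates.sort()
    parent = {cid: cid for cid in cids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    merged_any = 0
    for _, c1, c2 in candidates:
        r1, r2 = find(c1), find(c2)
        if r1 != r2:
            parent[max(r1, r2)] = min(r1, r2)
            merged_any += 1
    groups: dict[str, list[str]] = {}
    for cid in cids:
        groups.setdefault(find(cid), []).append(cid)
    new_contigs = {}
    for root in sorted(groups):
        members_ids: list[str] = []
        for cid in groups[root]:
            members_ids.extend(pmap.contigs[cid].clone_ids)
        if len(groups[root]) == 1:
            new_contigs[root] = pmap.contigs[root]
        else:
            members = layout_contig(sorted(members_ids), cache, max_log10)
            new_contigs[root] = Contig(root, members, max_log10)
    if merged_any:
        log.append(f"{mode} at 1e{max_log10:.0f}: {merged_any} merges")
    # renumber for determinism
    final = {}
    for k, root in enumerate(sorted(new_contigs), 1):
        ctg = new_contigs[root]
        final[f"ctg{k}"] = Contig(f"ctg{k}", ctg.members, ctg.built_log10)
    return PhysicalMap(final, list(pmap.singletons), pmap.params, log)


def _shares_linkage(
    m1: Sequence[tuple[str, float]],
    m2: Sequence[tuple[str, float]],
    cm_window: float,
) -> bool:
    for lg1, cm1 in m1:
        for lg2, cm2 in m2:
            if lg1 == lg2 and abs(cm1 - cm2) <= cm_window:
                return True
    return False


def contig_summary(
    pmap: PhysicalMap, bins: Sequence[int] = (5, 15, 100)
) -> dict:
    """Per-contig clone counts, CB lengths and Q fractions, plus a clone
    count histogram over configurable bin upper edges."""
    import pandas as pd

    rows = [
        {
            "contig": cid,
            "n_clones": len(c.members),
            "length_cb": c.length_cb,
            "q_fraction": round(c.q_fraction, 4),
        }
        for cid, c in sorted(pmap.contigs.items())
    ]
    table = pd.DataFrame(rows, columns=["contig", "n_clones", "length_cb", "q_fraction"])
    edges = list(bins)
    labels = (
        [f"<={edges[0]}"]
        + [f"{a + 1}-{b}" for a, b in zip(edges, edges[1:])]
        + [f">{edges[-1]}"]
    )
    counts = dict.fromkeys(labels, 0)
    for n in table["n_clones"] if len(table) else []:
        for i, e in enumerate(edges):
            if n <= e:
                counts[labels[i]] += 1
                break
        else:
            counts[labels[-1]] += 1
    return {
        "table": table,
        "histogram": counts,
        "total_clones": int(table["n_clones"].sum()) + len(pmap.singletons)
        if len(table)
        else len(pmap.singletons),
        "n_contigs": len(pmap.contigs),
        "n_singletons": len(pmap.singletons),
    }
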