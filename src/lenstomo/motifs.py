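"""Geometric motif detection and molecular mass estimation.

Particles decorating the lens cytoskeleton arrange into recognizable
geometric patterns: *files* (near-collinear, evenly spaced runs along a
filament), isosceles/equilateral triangles where two decorated filaments
approach, squares and tetrahedra ("bead" clusters), and pyramids
(square plus apex).  Motif search is restricted to the connection graph,
so every motif edge is an existing connection and edge lengths are
bounded by the pair-type cutoffs.

Molecular masses are estimated from particle volumes with the standard
protein density of 0.0013 nm^3 per Dalton.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

PROTEIN_NM3_PER_DALTON = 0.0013


@dataclass
class MassEstimate:
    volume_nm3: float
    mass_da: float
    mass_kda_rounded: int
    particle_id: int | None = None


def estimate_mass(volume_nm3: float,
                  nm3_per_dalton: float = PROTEIN_NM3_PER_DALTON,
                  particle_id: int | None = None) -> MassEstimate:
    """Molecular mass from a particle volume: mass = V / 0.0013 Da."""
    if volume_nm3 <= 0:
        raise ValueError("volume must be > 0")
    mass = volume_nm3 / nm3_per_dalton
    return MassEstimate(volume_nm3=float(volume_nm3), mass_da=float(mass),
                        mass_kda_rounded=int(round(mass / 1000.0)),
                        particle_id=particle_id)


@dataclass
class Motif:
    kind: str                       # file | isosceles_triangle | square |
                                    # tetrahedron | pyramid
    member_ids: tuple
    edge_lengths: list
    geometric_score: float          # 0 = perfect; relative deviation scale
    equilateral: bool = False       # triangles only

    def __post_init__(self) -> None:
        minimum = {"file": 3, "isosceles_triangle": 3, "square": 4,
                   "tetrahedron": 4, "pyramid": 5}[self.kind]
        if self.kind == "file":
            if len(self.member_ids) < minimum:
                raise ValueError("a file needs at least 3 members")
        elif len(self.member_ids) != minimum:
            raise ValueError(f"{self.kind} needs exactly {minimum} members")


def _positions(particles: pd.DataFrame) -> dict:
    return {int(r.id): np.array([r.x_nm, r.y_nm, r.z_nm])
            for r in particles.itertuples()}


def _adjacency(connections: pd.DataFrame) -> tuple[dict, dict]:
    adj: dict = {}
    elen: dict = {}
    for r in connections.itertuples():
        a, b = int(r.a), int(r.b)
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
        elen[(min(a, b), max(a, b))] = float(r.distance_nm)
    return adj, elen


def _point_line_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    d = b - a
    n = np.linalg.norm(d)
    if n < 1e-12:
        return float(np.linalg.norm(p - a))
    return float(np.linalg.norm(np.cross(p - a, d)) / n)


def detect_files(particles: pd.DataFrame, connections: pd.DataFrame,
                 collinearity_tol: float = 1.5,
                 spacing_tol: float = 0.2) -> list:
    """Find maximal near-collinear, evenly spaced chains (>= 3 members).

    Chains grow greedily from every connection: a neighbor ``c`` extends
    the chain ``... p, q`` when the interior point ``q`` lies within
    ``collinearity_tol`` (nm) of the line through ``p`` and ``c`` and the
    new spacing agrees with the chain's mean spacing within the
    ``spacing_tol`` fraction.  Chains whose member set is contained in a
    longer chain are dropped.
    """
    pos = _positions(particles)
    adj, elen = _adjacency(connections)

    def edge_len(u, v):
        return elen[(min(u, v), max(u, v))]

    def extend(chain: list) -> list:
        chain = list(chain)
        improved = True
        while improved:
            improved = False
            for tail in (True, False):
                if not tail:
                    chain.reverse()
                q, p = chain[-1], chain[-2]
                spacings = [edge_len(u, v) for u, v in zip(chain[:-1], chain[1:])]
                ref = float(np.mean(spacings))
                best, best_dev = None, None
                for c in sorted(adj.get(q, ())):
                    if c in chain:
                        continue
                    dev = _point_line_distance(pos[q], pos[p], pos[c])
                    if dev > collinearity_tol:
                        continue
                    if abs(edge_len(q, c) - ref) > spacing_tol * ref:
                        continue
                    if best is None or dev < best_dev:
                        best, best_dev = c, dev
                if best is not None:
                    chain.append(best)
                    improved = True
                if not tail:
                    chain.reverse()
        return chain

    chains = {}
    for r in connections.itertuples():
        chain = extend([int(r.a), int(r.b)])
        if len(chain) < 3:
            continue
        if chain[0] > chain[-1]:
            chain.reverse()
        chains[tuple(chain)] = frozenset(chain)

    # drop chains contained in longer ones
    keep = []
    for chain, members in chains.items():
        if not any(members < other for other in chains.values()):
            keep.append(chain)

    motifs = []
    for chain in sorted(set(keep)):
        spacings = [edge_len(u, v) for u, v in zip(chain[:-1], chain[1:])]
        devs = [_point_line_distance(pos[q], pos[p], pos[c])
                for p, q, c in zip(chain[:-2], chain[1:-1], chain[2:])]
        score = max(devs) / collinearity_tol if devs else 0.0
        motifs.append(Motif(kind="file", member_ids=tuple(chain),
                            edge_lengths=spacings, geometric_score=score))
    return motifs


def _rel_spread(lengths) -> float:
    m = float(np.mean(lengths))
    return float(max(abs(l - m) for l in lengths) / m)


def _edges_equal(l1: float, l2: float, tol: float) -> bool:
    return abs(l1 - l2) <= tol * (l1 + l2) / 2.0


def detect_polyhedra(particles: pd.DataFrame, connections: pd.DataFrame,
                     edge_tol: float = 0.2,
                     planarity_tol: float = 1.5) -> list:
    """Detect triangles, squares, tetrahedra and pyramids in the network.

    * isosceles triangle: 3-clique with >= 2 edges equal within the
      ``edge_tol`` fraction (equilateral flagged when all 3 are equal);
    * tetrahedron: 4-clique whose 6 edges all lie within ``edge_tol`` of
      their mean;
    * square: 4-cycle with 4 near-equal sides, near-equal diagonals of
      ~sqrt(2) side length, and the 4 points coplanar within
      ``planarity_tol`` nm (diagonals need not be connections);
    * pyramid: detected square plus an apex connected to all 4 corners
      with near-equal apex edges.

    ``geometric_score`` is the maximum relative edge deviation (0 best).
    """
    pos = _positions(particles)
    adj, elen = _adjacency(connections)

    def edge_len(u, v):
        return elen[(min(u, v), max(u, v))]

    motifs = []

    # triangles and tetrahedra via clique enumeration
    triangles = []
    for (a, b), _ in sorted(elen.items()):
        for c in sorted(adj[a] & adj[b]):
            if c > b:
                triangles.append((a, b, c))
    for a, b, c in triangles:
        e = [edge_len(a, b), edge_len(b, c), edge_len(a, c)]
        pairs_equal = sum(_edges_equal(e[i], e[j], edge_tol)
                          for i, j in ((0, 1), (1, 2), (0, 2)))
        if pairs_equal >= 1:
            motifs.append(Motif(kind="isosceles_triangle", member_ids=(a, b, c),
                                edge_lengths=e, geometric_score=_rel_spread(e),
                                equilateral=pairs_equal == 3))

    for a, b, c in triangles:
        for d in sorted(adj[a] & adj[b] & adj[c]):
            if d <= c:
                continue
            e = [edge_len(u, v) for u, v in
                 itertools.combinations((a, b, c, d), 2)]
            spread = _rel_spread(e)
            if spread <= edge_tol:
                motifs.append(Motif(kind="tetrahedron", member_ids=(a, b, c, d),
                                    edge_lengths=e, geometric_score=spread))

    # squares: cycle a-b-c-d around diagonal pair (a, c) x (b, d)
    squares = []
    seen = set()
    nodes = sorted(adj)
    for a, c in itertools.combinations(nodes, 2):
        common = sorted(adj[a] & adj[c])
        for b, d in itertools.combinations(common, 2):
            key = frozenset((a, b, c, d))
            if key in seen:
                continue
            sides = [edge_len(a, b), edge_len(b, c), edge_len(c, d), edge_len(d, a)]
            if _rel_spread(sides) > edge_tol:
                continue
            side = float(np.mean(sides))
            diag1 = float(np.linalg.norm(pos[a] - pos[c]))
            diag2 = float(np.linalg.norm(pos[b] - pos[d]))
            if not _edges_equal(diag1, diag2, edge_tol):
                continue
            if abs((diag1 + diag2) / 2.0 - math.sqrt(2.0) * side) > edge_tol * side:
                continue
            n = np.cross(pos[b] - pos[a], pos[c] - pos[a])
            nn = np.linalg.norm(n)
            if nn > 1e-12 and abs(np.dot(pos[d] - pos[a], n / nn)) > planarity_tol:
                continue
            seen.add(key)
            score = max(_rel_spread(sides), abs(diag1 - diag2) / ((diag1 + diag2) / 2))
            squares.append(((a, b, c, d), sides, score))
            motifs.append(Motif(kind="square", member_ids=(a, b, c, d),
                                edge_lengths=sides, geometric_score=score))

    # pyramids: square + apex connected to all four corners
    for (corners, sides, sq_score) in squares:
        corner_set = set(corners)
        candidates = set.intersection(*(adj[c] for c in corners)) - corner_set
        for apex in sorted(candidates):
            apex_edges = [edge_len(apex, c) for c in corners]
            if _rel_spread(apex_edges) > edge_tol:
                continue
            score = max(sq_score, _rel_spread(apex_edges))
            motifs.append(Motif(kind="pyramid",
                                member_ids=tuple(corners) + (apex,),
                                edge_lengths=sides + apex_edges,
                                geometric_score=score))
    return motifs


def motif_counts(motifs: list) -> dict:
    out = {"file": 0, "isosceles_triangle": 0, "equilateral_triangle": 0,
           "square": 0, "tetrahedron": 0, "pyramid": 0}
    for m in motifs:
        out[m.kind] += 1
        if m.kind == "isosceles_triangle" and m.equilateral:
            out["equilateral_triangle"] += 1
    return out


def motifs_to_frame(motifs: list) -> pd.DataFrame:
    return pd.DataFrame([{
        "kind": m.kind,
        "member_ids": ",".join(str(i) for i in m.member_ids),
        "n_members": len(m.member_ids),
        "mean_edge_nm": float(np.mean(m.edge_lengths)) if m.edge_lengths else np.nan,
        "geometric_score": m.geometric_score,
        "equilateral": m.equilateral,
    } for m in motifs])
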