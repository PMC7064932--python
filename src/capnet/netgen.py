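"""Arteriolar tree generation with controlled bifurcation asymmetry.

Builds rooted binary trees of cylindrical vessel segments from a first-order
arteriole (default 75 um) down to terminal arterioles (default mean ~11 um,
214 terminals). The generator is constraint-driven rather than a
reconstruction of a measured tree, and separates three ingredients:

* **Topology** — the terminal count is split near-evenly (ceil/floor) at
  every node, so all 214 terminals sit at depth 7-8 and every terminal
  count is reachable exactly.
* **Flow-balanced reference diameters** — daughter diameters satisfy
  ``Da^2 + Db^2 = area_ratio * Dp^2`` and their ratio is calibrated, using
  the two-phase flow solver itself, so that with no asymmetry every
  bifurcation splits blood flow exactly 50:50. Vessels are thereby sized to
  the demand they feed (a Murray-like principle expressed functionally).
* **Asymmetry** — a seeded folded-normal perturbation of the daughter
  diameter ratio around the reference, of random sign, with the network
  mean pinned to the requested value. Bifurcation "asymmetry" throughout
  this package means this perturbation: the relative daughter-diameter
  difference in excess of the flow-balanced reference ratio.

The hyperinsulinemia-like variant of a network is produced by
:func:`rescale_asymmetry`, which keeps topology, reference ratios and
segment lengths fixed and scales every bifurcation's asymmetry — a paired
within-network intervention.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "NetworkSpec",
    "VesselSegment",
    "ArteriolarTree",
    "build_tree",
    "rescale_asymmetry",
    "write_tree",
    "read_tree",
]


@dataclass(frozen=True)
class NetworkSpec:
    """Morphometric targets and generator knobs for one arteriolar tree."""

    root_diameter: float = 75.0            # um
    terminal_diameter_target: float = 11.0  # um, mean over terminals
    n_terminals_target: int = 214
    asymmetry_mean: float = 0.07           # BN default; 0.055 for SHI
    daughter_area_ratio: float = 1.22      # (Da^2+Db^2)/Dp^2; refined by build_tree's search
    length_per_diameter: float = 13.66     # segment length = ratio * diameter
    asymmetry_sd_frac: float = 0.35        # sd of the folded normal / its mean
    topology_skew: float = 8.0             # Beta(a,a) split of terminal counts; inf = even
    rng_seed: int = 20190                  # the frozen reference realization

    def __post_init__(self) -> None:
        if not (self.root_diameter > self.terminal_diameter_target > 0):
            raise ValueError("need root_diameter > terminal_diameter_target > 0")
        if not (0.0 <= self.asymmetry_mean < 1.0):
            raise ValueError("asymmetry_mean must be in [0, 1)")
        if self.n_terminals_target < 1:
            raise ValueError("n_terminals_target must be >= 1")
        if self.daughter_area_ratio <= 0 or self.length_per_diameter <= 0:
            raise ValueError("area ratio and length ratio must be positive")


@dataclass
class VesselSegment:
    id: int
    diameter: float          # um
    length: float            # um
    parent_id: int | None = None
    daughter_ids: tuple[int, int] | None = None

    @property
    def is_terminal(self) -> bool:
        return self.daughter_ids is None


@dataclass
class ArteriolarTree:
    """Rooted binary tree of vessel segments (diverging arterioles only).

    ``meta`` carries the generating spec, the calibrated area ratio, the
    flow-balanced reference daughter ratios per bifurcation, and the
    asymmetry perturbations actually applied.
    """

    segments: dict[int, VesselSegment]
    root_id: int
    meta: dict = field(default_factory=dict)

    @property
    def terminal_ids(self) -> list[int]:
        return [s.id for s in self.segments.values() if s.is_terminal]

    @property
    def n_terminals(self) -> int:
        return sum(1 for s in self.segments.values() if s.is_terminal)

    def mean_terminal_diameter(self) -> float:
        return float(np.mean([self.segments[i].diameter for i in self.terminal_ids]))

    def _reference_ratio(self, bif_id: int) -> float:
        refs = self.meta.get("reference_ratios", {})
        return float(refs.get(bif_id, refs.get(str(bif_id), 1.0)))

    def bifurcation_asymmetries(self) -> np.ndarray:
        """Per-bifurcation asymmetry: the relative daughter-diameter
        difference in excess of the flow-balanced reference ratio, i.e.
        ``a`` such that ``Da/Db = r0 * (2+a)/(2-a)`` (so for ``r0 = 1`` it
        reduces to ``|Da-Db| / mean(Da, Db)``). Returned in id order.
        """
        out = []
        for s in sorted(self.segments.values(), key=lambda s: s.id):
            if s.daughter_ids is None:
                continue
            da = self.segments[s.daughter_ids[0]].diameter
            db = self.segments[s.daughter_ids[1]].diameter
            v = (da / db) / self._reference_ratio(s.id)
            out.append(abs(2.0 * (v - 1.0) / (v + 1.0)))
        return np.asarray(out)

    def total_volume(self) -> float:
        """Total vascular volume in um^3."""
        return sum(math.pi * (s.diameter / 2.0) ** 2 * s.length for s in self.segments.values())

    def validate(self) -> None:
        ids = set(self.segments)
        root = self.segments[self.root_id]
        if root.parent_id is not None:
            raise ValueError("root has a parent")
        seen = set()
        stack = [self.root_id]
        while stack:
            i = stack.pop()
            if i in seen:
                raise ValueError(f"cycle involving segment {i}")
            seen.add(i)
            s = self.segments[i]
            if s.diameter <= 0 or s.length <= 0:
                raise ValueError(f"segment {i}: nonpositive diameter or length")
            if s.daughter_ids is not None:
                if len(s.daughter_ids) != 2:
                    raise ValueError(f"segment {i}: must have 0 or 2 daughters")
                for d in s.daughter_ids:
                    if d not in ids:
                        raise ValueError(f"segment {i}: unknown daughter {d}")
                    if self.segments[d].parent_id != i:
                        raise ValueError(f"segment {d}: parent link mismatch")
                    if self.segments[d].diameter > s.diameter + 1e-9:
                        raise ValueError(f"segment {d}: daughter wider than parent")
                    stack.append(d)
        if seen != ids:
            raise ValueError("tree is not connected to the root")


def _daughter_diameters_ratio(Dp: float, r: float, area_ratio: float) -> tuple[float, float]:
    """Daughters with diameter ratio ``r = Da/Db`` under the area constraint."""
    da = Dp * math.sqrt(area_ratio * r * r / (1.0 + r * r))
    da = min(da, 0.995 * Dp)
    return da, da / r


def _topology(spec: NetworkSpec) -> list[tuple[int, int, int, int, int]]:
    """Seeded preorder topology: (bif id, daughter a id, daughter b id, na, nb).

    Terminal counts are split by a Beta(skew, skew) fraction at every node
    (clipped so both daughters keep at least one terminal), giving the
    variable path depths of real arteriolar trees — terminals are reached
    after different numbers of bifurcations depending on the flow path.
    Node ids follow creation order in :func:`_grow`. The draw stream is
    derived from the spec seed but separate from the asymmetry stream, so
    topology and asymmetry can be varied independently.
    """
    rng = np.random.default_rng((spec.rng_seed, 1))
    order = []
    stack = [(0, spec.n_terminals_target)]
    next_id = 1
    while stack:
        i, n = stack.pop()
        if n <= 1:
            continue
        if np.isinf(spec.topology_skew):
            na = (n + 1) // 2
        else:
            p = rng.beta(spec.topology_skew, spec.topology_skew)
            na = int(np.clip(round(n * p), 1, n - 1))
        nb = n - na
        ia, ib = next_id, next_id + 1
        next_id += 2
        order.append((i, ia, ib, na, nb))
        stack.append((ib, nb))
        stack.append((ia, na))
    return order


def _grow(spec: NetworkSpec, area_ratio: float, ref_ratios: dict[int, float],
          asymmetries: dict[int, float],
          topo: list[tuple[int, int, int, int, int]] | None = None) -> ArteriolarTree:
    """Assemble the tree from topology, reference ratios and signed asymmetries."""
    if topo is None:
        topo = _topology(spec)
    segments: dict[int, VesselSegment] = {}

    def new_segment(i: int, D: float, parent: int | None) -> None:
        segments[i] = VesselSegment(id=i, diameter=D, length=spec.length_per_diameter * D,
                                    parent_id=parent)

    new_segment(0, spec.root_diameter, None)
    for i, ia, ib, _na, _nb in topo:
        a = asymmetries.get(i, 0.0)
        r = ref_ratios.get(i, 1.0) * (2.0 + a) / (2.0 - a)
        s = segments[i]
        if r >= 1.0:
            da, db = _daughter_diameters_ratio(s.diameter, r, area_ratio)
        else:
            db, da = _daughter_diameters_ratio(s.diameter, 1.0 / r, area_ratio)
        new_segment(ia, da, i)
        new_segment(ib, db, i)
        s.daughter_ids = (ia, ib)
    return ArteriolarTree(
        segments=segments, root_id=0,
        meta={"spec": spec.__dict__.copy(), "area_ratio": area_ratio,
              "reference_ratios": dict(ref_ratios)})


def _draw_asymmetries(spec: NetworkSpec, topo) -> dict[int, float]:
    rng = np.random.default_rng(spec.rng_seed)
    sd = spec.asymmetry_mean * spec.asymmetry_sd_frac
    out = {}
    for i, *_ in topo:
        if spec.asymmetry_mean == 0:
            out[i] = 0.0
            continue
        a = abs(rng.normal(spec.asymmetry_mean, sd)) if sd > 0 else spec.asymmetry_mean
        a = min(a, 0.4)
        out[i] = a if rng.random() < 0.5 else -a
    return out


def _calibrate_reference(spec: NetworkSpec, area_ratio: float, topo,
                         warm: dict[int, float] | None = None,
                         max_rounds: int = 40, tol: float = 1e-7) -> dict[int, float]:
    """Daughter ratios making every bifurcation split blood flow 50:50.

    Fixed point over the full two-phase solver (so viscosity and phase
    separation feedbacks are included): measure each bifurcation's flow
    split on the zero-asymmetry tree, correct the ratio by the cube root of
    the conductance error, repeat.
    """
    from .flow_solver import BoundaryConditions, solve  # deferred: avoid cycle

    refs = dict(warm) if warm else {i: 1.0 for i, *_ in topo}
    bc = BoundaryConditions(12.0, 0.42)
    zero = {i: 0.0 for i in refs}
    for _ in range(max_rounds):
        tree = _grow(spec, area_ratio, refs, zero, topo)
        state = solve(tree, bc)
        worst = 0.0
        for i in refs:
            ia, ib = tree.segments[i].daughter_ids
            qa = state.table.loc[ia, "blood_flow_nl_s"]
            qb = state.table.loc[ib, "blood_flow_nl_s"]
            worst = max(worst, abs(qa / (qa + qb) - 0.5))
            refs[i] *= (qb / qa) ** (1.0 / 3.0)
        if worst < tol:
            break
    return refs


def build_tree(spec: NetworkSpec) -> ArteriolarTree:
    """Generate a tree meeting the spec's targets.

    The terminal count is met exactly by construction. The daughter area
    ratio (the per-generation diameter-reduction constant) is bisected —
    with the flow-balanced reference re-calibrated at each step — until the
    mean terminal diameter matches its target; generation fails with a
    diagnostic if the bounded search cannot reach +-10%. The realized mean
    bifurcation asymmetry is pinned to the requested mean exactly.
    """
    topo = _topology(spec)
    asym = _draw_asymmetries(spec, topo)
    if spec.asymmetry_mean > 0:
        mean = float(np.mean([abs(a) for a in asym.values()]))
        asym = {i: a * spec.asymmetry_mean / mean for i, a in asym.items()}
    lo, hi = 1.02, 1.60
    refs: dict[int, float] | None = None
    tree = None
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        refs = _calibrate_reference(spec, mid, topo, warm=refs)
        tree = _grow(spec, mid, refs, asym, topo)
        mtd = tree.mean_terminal_diameter()
        if abs(mtd - spec.terminal_diameter_target) < 1e-5:
            break
        if mtd < spec.terminal_diameter_target:
            lo = mid
        else:
            hi = mid
    mtd = tree.mean_terminal_diameter()
    if abs(mtd - spec.terminal_diameter_target) > 0.10 * spec.terminal_diameter_target:
        raise RuntimeError(
            f"area-ratio search failed: mean terminal diameter {mtd:.2f} um is outside "
            f"+-10% of {spec.terminal_diameter_target} um (last area ratio {mid:.3f})")
    if tree.n_terminals != spec.n_terminals_target:
        raise RuntimeError("terminal count mismatch (internal error)")
    tree.meta["asymmetries"] = dict(asym)
    tree.validate()
    return tree


def _rebuild_with_asymmetries(tree: ArteriolarTree, scale: float) -> ArteriolarTree:
    """Recompute diameters with every asymmetry multiplied by ``scale``.

    Topology, reference ratios and segment lengths are preserved exactly.
    """
    spec = NetworkSpec(**tree.meta["spec"])
    area_ratio = tree.meta["area_ratio"]
    refs = {int(k): float(v) for k, v in tree.meta["reference_ratios"].items()}
    old = tree.segments
    asym = {}
    for i, s in old.items():
        if s.daughter_ids is None:
            continue
        da, db = old[s.daughter_ids[0]].diameter, old[s.daughter_ids[1]].diameter
        v = (da / db) / refs.get(i, 1.0)
        asym[i] = 2.0 * (v - 1.0) / (v + 1.0) * scale
    out = _grow(spec, area_ratio, refs, asym)
    # lengths are preserved from the source tree, not recomputed
    for i, s in out.segments.items():
        s.length = old[i].length
    out.meta = dict(tree.meta)
    out.meta["asymmetries"] = asym
    out.meta["asymmetry_scale"] = tree.meta.get("asymmetry_scale", 1.0) * scale
    return out


def rescale_asymmetry(tree: ArteriolarTree, new_asymmetry_mean: float) -> ArteriolarTree:
    """Return a topology- and length-identical tree with rescaled asymmetry.

    Every bifurcation's asymmetry (daughter-ratio perturbation around the
    flow-balanced reference) is multiplied by ``new_asymmetry_mean /
    current_mean``. Diameter changes are second order in the asymmetry, so
    total vascular volume changes well under 1% for the default networks.
    """
    if new_asymmetry_mean < 0:
        raise ValueError("asymmetry mean must be nonnegative")
    asyms = tree.bifurcation_asymmetries()
    old_mean = float(asyms.mean()) if asyms.size else 0.0
    if old_mean == 0.0:
        if new_asymmetry_mean == 0.0:
            return _rebuild_with_asymmetries(tree, 1.0)
        raise ValueError("cannot rescale a perfectly symmetric tree to nonzero asymmetry")
    out = _rebuild_with_asymmetries(tree, new_asymmetry_mean / old_mean)
    out.meta["asymmetry_mean"] = new_asymmetry_mean
    return out


# ---------------------------------------------------------------------------
# JSON serialization: {"root_id": int, "segments": [{id, parent_id,
#   daughter_ids, diameter_um, length_um}, ...], "meta": {...}}

def write_tree(tree: ArteriolarTree, path: str | Path) -> None:
    meta = dict(tree.meta)
    if "reference_ratios" in meta:
        meta["reference_ratios"] = {str(k): v for k, v in meta["reference_ratios"].items()}
    if "asymmetries" in meta:
        meta["asymmetries"] = {str(k): v for k, v in meta["asymmetries"].items()}
    payload = {
        "root_id": tree.root_id,
        "meta": meta,
        "segments": [
            {
                "id": s.id,
                "parent_id": s.parent_id,
                "daughter_ids": list(s.daughter_ids) if s.daughter_ids else None,
                "diameter_um": s.diameter,
                "length_um": s.length,
            }
            for s in sorted(tree.segments.values(), key=lambda s: s.id)
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_tree(path: str | Path) -> ArteriolarTree:
    data = json.loads(Path(path).read_text())
    segments = {}
    for rec in data["segments"]:
        try:
            seg = VesselSegment(
                id=int(rec["id"]),
                diameter=float(rec["diameter_um"]),
                length=float(rec["length_um"]),
                parent_id=None if rec.get("parent_id") is None else int(rec["parent_id"]),
                daughter_ids=tuple(rec["daughter_ids"]) if rec.get("daughter_ids") else None,
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"malformed segment record {rec!r}: {exc}") from exc
        if seg.diameter <= 0:
            raise ValueError(f"segment {seg.id}: diameter must be positive, got {seg.diameter}")
        if seg.length <= 0:
            raise ValueError(f"segment {seg.id}: length must be positive, got {seg.length}")
        segments[seg.id] = seg
    meta = data.get("meta", {})
    if "reference_ratios" in meta:
        meta["reference_ratios"] = {int(k): float(v) for k, v in meta["reference_ratios"].items()}
    if "asymmetries" in meta:
        meta["asymmetries"] = {int(k): float(v) for k, v in meta["asymmetries"].items()}
    tree = ArteriolarTree(segments=segments, root_id=int(data["root_id"]), meta=meta)
    tree.validate()
    return tree
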