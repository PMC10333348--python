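"""Synthetic phantoms: parcellation atlases, coalescent lesions with known
per-ROI overlap, ADC maps with CSF-bright ventricles, and labeled cohorts.

The phantom brain is an ellipsoid partitioned by a mirrored-seed Voronoi
tessellation: every bilateral ROI is one label shared by a seed and its
midline mirror (plus one unpaired midline ROI, the brainstem analogue), so
the atlas reproduces the bilateral-ROI structure and the spatial adjacency
that makes infarct features coalescent. Lesions are grown as connected
regions that hit requested per-ROI overlap fractions, spilling mildly into
neighbors the way real infarcts cross semantic boundaries. Every generator
is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import ndimage

from .core_io import BinaryLesionMask, LabelRow, LabeledVolume, ScalarVolume, VolumeGrid
from .models import LabeledCase, make_case
from .qfv import extract_qfv

__all__ = [
    "PhantomSpec",
    "PhantomAtlas",
    "make_phantom_atlas",
    "make_lesion",
    "make_cohort",
    "make_adc_phantom",
    "make_aspects_phantom",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Conditions for one phantom study.

    The defaults define the package's reference study: a 48^3 1 mm grid, 8
    bilateral arterial-like territories, 6 bilateral structural ROIs plus a
    midline brainstem analogue, lesions drawn on the structural scheme with
    per-ROI prevalence 0.45 and overlap fractions in [0.10, 0.30], labels
    from the tau = 0.05 involvement rule with 5% label noise. Near-balanced
    prevalence keeps every ROI's label learnable under the 5% noise: the
    noise-limited balanced-accuracy ceiling is highest for balanced classes
    and degrades quickly for rare (or near-universal) labels.
    """

    shape: tuple[int, int, int] = (48, 48, 48)
    n_arterial_pairs: int = 8
    n_structural_pairs: int = 6
    ventricle_size: tuple[int, int, int] = (12, 16, 8)
    lesion_fraction_low: float = 0.10
    lesion_fraction_high: float = 0.30
    label_rule_tau: float = 0.05
    label_noise: float = 0.05
    prevalence: float = 0.45
    overlap_tol: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("lesion_fraction_low", "lesion_fraction_high",
                     "label_rule_tau", "label_noise", "prevalence", "overlap_tol"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if min(self.shape) < 32:
            raise ValueError("phantom grid must be at least 32 voxels per axis")
        if self.n_arterial_pairs < 2 or self.n_structural_pairs < 2:
            raise ValueError("need at least 2 ROI pairs per scheme")


@dataclass
class PhantomAtlas:
    arterial: LabeledVolume
    structural: LabeledVolume
    ventricles: LabeledVolume
    brain: BinaryLesionMask


def _centered_grid(shape: tuple[int, int, int]) -> VolumeGrid:
    # 1 mm isotropic, world origin at the volume center so x = 0 is the midline
    affine = np.eye(4)
    affine[:3, 3] = -(np.asarray(shape) - 1) / 2.0
    return VolumeGrid(shape=shape, affine=affine)


def _ellipsoid_brain(shape: tuple[int, int, int]) -> np.ndarray:
    c = (np.asarray(shape) - 1) / 2.0
    semi = np.asarray(shape) * 0.45
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    return (
        ((ii - c[0]) / semi[0]) ** 2
        + ((jj - c[1]) / semi[1]) ** 2
        + ((kk - c[2]) / semi[2]) ** 2
    ) <= 1.0


def _assign_nearest(brain: np.ndarray, seeds: list) -> np.ndarray:
    shape = brain.shape
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    best = np.full(shape, np.inf)
    labels = np.zeros(shape, dtype=np.int32)
    for label, s in seeds:
        d2 = (ii - s[0]) ** 2 + (jj - s[1]) ** 2 + (kk - s[2]) ** 2
        closer = d2 < best
        labels[closer] = label
        best = np.minimum(best, d2)
    labels[~brain] = 0
    return labels


def _mirrored_voronoi(
    brain: np.ndarray,
    n_pairs: int,
    rng: np.random.Generator,
    midline_roi: bool,
    relax_iters: int = 8,
) -> np.ndarray:
    """Centroidal Voronoi labels over the brain from mirrored seed pairs (one
    shared label per pair) plus, optionally, one unpaired low-central midline
    seed. Lloyd relaxation evens out cell volumes, mirroring the roughly
    comparable ROI sizes of real parcellations."""
    shape = brain.shape
    half = (shape[0] - 1) / 2.0
    coords = np.argwhere(brain)
    right = coords[coords[:, 0] > half + 2]
    chosen = rng.choice(len(right), size=n_pairs, replace=False)
    pair_seeds = {label: right[idx].astype(float)
                  for label, idx in enumerate(chosen, start=1)}
    mid_label = n_pairs + 1 if midline_roi else None
    mid_seed = np.array([half, (shape[1] - 1) / 2.0, shape[2] * 0.18])

    def seed_list():
        seeds = []
        for label, s in pair_seeds.items():
            mirror = s.copy()
            mirror[0] = 2 * half - s[0]
            seeds.append((label, s))
            seeds.append((label, mirror))
        if mid_label is not None:
            seeds.append((mid_label, mid_seed))
        return seeds

    labels = _assign_nearest(brain, seed_list())
    for _ in range(relax_iters):
        moved = False
        for label in pair_seeds:
            cell = np.argwhere((labels == label) & (np.arange(shape[0])[:, None, None] > half))
            if len(cell) == 0:
                continue
            centroid = cell.mean(axis=0)
            if not np.allclose(centroid, pair_seeds[label], atol=0.25):
                pair_seeds[label] = centroid
                moved = True
        if mid_label is not None:
            cell = np.argwhere(labels == mid_label)
            if len(cell):
                centroid = cell.mean(axis=0)
                centroid[0] = half  # stay on the midline
                if not np.allclose(centroid, mid_seed, atol=0.25):
                    mid_seed[:] = centroid
                    moved = True
        if not moved:
            break
        labels = _assign_nearest(brain, seed_list())
    return labels


def _ventricle_labels(
    shape: tuple[int, int, int], size: tuple[int, int, int]
) -> np.ndarray:
    """Five lateral-ventricle sub-regions: a central box split into five
    slabs along the anterior-posterior axis."""
    c = (np.asarray(shape) - 1) / 2.0
    labels = np.zeros(shape, dtype=np.int32)
    x0 = int(round(c[0] - size[0] / 2))
    y0 = int(round(c[1] - size[1] / 2))
    z0 = int(round(c[2] - size[2] / 2))
    edges = np.linspace(0, size[1], 6).round().astype(int)
    for sub in range(5):
        labels[
            x0 : x0 + size[0],
            y0 + edges[sub] : y0 + edges[sub + 1],
            z0 : z0 + size[2],
        ] = sub + 1
    return labels


def make_phantom_atlas(spec: PhantomSpec) -> PhantomAtlas:
    """Build the arterial-like and structural-like parcellations, the
    five-part ventricle atlas, and the brain mask, all on one grid."""
    rng = np.random.default_rng(spec.seed)
    grid = _centered_grid(spec.shape)
    brain = _ellipsoid_brain(spec.shape)

    art = _mirrored_voronoi(brain, spec.n_arterial_pairs, rng, midline_roi=False)
    struct = _mirrored_voronoi(brain, spec.n_structural_pairs, rng, midline_roi=True)
    vent = _ventricle_labels(spec.shape, spec.ventricle_size)
    vent[~brain] = 0

    art_table = [
        LabelRow(i, f"territory_{i}", "arterial")
        for i in range(1, spec.n_arterial_pairs + 1)
    ]
    struct_table = [
        LabelRow(i, f"structure_{i}", "structural")
        for i in range(1, spec.n_structural_pairs + 1)
    ] + [LabelRow(spec.n_structural_pairs + 1, "brainstem", "structural")]
    vent_table = [LabelRow(i, f"ventricle_{i}", "ventricle") for i in range(1, 6)]

    return PhantomAtlas(
        arterial=LabeledVolume(grid=grid, labels=art, table=art_table),
        structural=LabeledVolume(grid=grid, labels=struct, table=struct_table),
        ventricles=LabeledVolume(grid=grid, labels=vent, table=vent_table),
        brain=BinaryLesionMask(grid=grid, values=brain.astype(np.uint8)),
    )


# ---------------------------------------------------------------------------
# Lesion growth
# ---------------------------------------------------------------------------

_NEIGH = ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1))


class _Frontier:
    """Frontier voxels bucketed by ROI label, with O(1) seeded sampling."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.buckets: dict[int, list] = {}
        self.index: dict[tuple[int, int, int], int] = {}
        self.label_of: dict[tuple[int, int, int], int] = {}

    def add(self, v, rid: int) -> None:
        if v in self.index:
            return
        bucket = self.buckets.setdefault(rid, [])
        self.index[v] = len(bucket)
        self.label_of[v] = rid
        bucket.append(v)

    def discard(self, v) -> None:
        i = self.index.pop(v, None)
        if i is None:
            return
        bucket = self.buckets[self.label_of.pop(v)]
        last = bucket.pop()
        if i < len(bucket):
            bucket[i] = last
            self.index[last] = i

    def sample_from(self, rids) -> tuple | None:
        """Uniform draw over the union of the given ROIs' buckets."""
        sizes = [len(self.buckets.get(r, ())) for r in rids]
        total = sum(sizes)
        if total == 0:
            return None
        k = int(self.rng.integers(total))
        for r, s in zip(rids, sizes):
            if k < s:
                return self.buckets[r][k]
            k -= s
        raise AssertionError("unreachable")

    def all_items(self):
        for bucket in self.buckets.values():
            yield from bucket


def make_lesion(
    atlas: LabeledVolume,
    targets: Mapping[str, float],
    tol: float = 0.02,
    seed: int = 0,
    spill: float = 0.03,
    max_iter: int | None = None,
) -> BinaryLesionMask:
    """Grow a connected lesion hitting the requested per-ROI overlap
    fractions within ``tol``; untargeted ROIs stay at or below ``tol``.

    Growth is stochastic dilation from a voxel inside the largest target,
    preferring under-quota target ROIs, bridging between disconnected
    targets along the in-brain shortest path, and finishing with a mild
    spillover pass (rate ``spill`` of the lesion size) into neighbors so the
    lesion coalesces across boundaries the way real infarcts do.
    """
    if not targets:
        raise ValueError("empty target map would produce an empty lesion")
    if tol <= 0:
        raise ValueError("tol must be positive")
    rng = np.random.default_rng(seed)
    labels = atlas.labels
    shape = labels.shape
    name_to_id = {row.name: row.id for row in atlas.table}
    for roi in targets:
        if roi not in name_to_id:
            raise KeyError(f"unknown ROI {roi!r}")
    sizes = atlas.voxel_counts()
    quotas = {
        name_to_id[roi]: int(round(frac * sizes[name_to_id[roi]]))
        for roi, frac in targets.items()
    }
    if any(q == 0 for q in quotas.values()):
        raise ValueError("a target fraction is below one voxel; increase it")
    # hard caps: quota + tol slack for targets, tol alone for the rest
    caps = {rid: quotas.get(rid, 0) + max(1, int(tol * sz))
            for rid, sz in sizes.items()}
    brain = labels > 0
    lesion = np.zeros(shape, dtype=bool)
    got = dict.fromkeys(sizes, 0)
    frontier = _Frontier(rng)
    budget = max_iter or 20 * (sum(quotas.values()) + 1000)
    dist_cache: dict[int, np.ndarray] = {}

    def add_voxel(v) -> None:
        lesion[v] = True
        got[int(labels[v])] += 1
        frontier.discard(v)
        for d in _NEIGH:
            w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            if (
                0 <= w[0] < shape[0]
                and 0 <= w[1] < shape[1]
                and 0 <= w[2] < shape[2]
                and brain[w]
                and not lesion[w]
            ):
                frontier.add(w, int(labels[w]))

    def bridge_to(rid: int) -> None:
        """Walk from the lesion to ROI `rid` along decreasing distance."""
        if rid not in dist_cache:
            dist_cache[rid] = ndimage.distance_transform_edt(labels != rid)
        dist = dist_cache[rid]
        # start from the frontier voxel closest to the target
        items = list(frontier.all_items())
        if not items:
            raise RuntimeError("lesion growth stuck: empty frontier")
        start = min(items, key=lambda v: dist[v])
        add_voxel(start)
        cur = start
        while dist[cur] > 0:
            steps = [
                (cur[0] + d[0], cur[1] + d[1], cur[2] + d[2]) for d in _NEIGH
            ]
            # the walk may pass through voxels that are already lesioned;
            # only strictly descending steps, so it always terminates
            steps = [
                w
                for w in steps
                if 0 <= w[0] < shape[0]
                and 0 <= w[1] < shape[1]
                and 0 <= w[2] < shape[2]
                and brain[w]
                and dist[w] < dist[cur]
            ]
            if not steps:
                raise RuntimeError("lesion growth stuck while bridging")
            cur = min(steps, key=lambda w: dist[w])
            if not lesion[cur]:
                add_voxel(cur)

    # start near the interior of the largest-quota target
    order = sorted(quotas, key=lambda r: -quotas[r])
    core = ndimage.binary_erosion(labels == order[0], iterations=2)
    pool = np.argwhere(core if core.any() else labels == order[0])
    add_voxel(tuple(int(c) for c in pool[rng.integers(len(pool))]))

    steps = 0
    while True:
        pending = [r for r in order if got[r] < quotas[r]]
        if not pending:
            break
        steps += 1
        if steps > budget:
            raise RuntimeError("lesion growth did not reach its targets")
        v = frontier.sample_from(pending)
        if v is None:
            bridge_to(pending[0])
            continue
        add_voxel(v)

    # mild spillover pass so the lesion coalesces into neighbors
    n_extra = int(round(spill * lesion.sum()))
    for _ in range(n_extra):
        open_rois = [
            rid for rid in sizes
            if rid not in quotas and got[rid] < caps[rid]
        ]
        v = frontier.sample_from(open_rois)
        if v is None:
            break
        add_voxel(v)

    return BinaryLesionMask(grid=atlas.grid, values=lesion.astype(np.uint8))


# ---------------------------------------------------------------------------
# Cohorts and ADC phantoms
# ---------------------------------------------------------------------------


def make_cohort(
    atlas: PhantomAtlas,
    n: int,
    prevalence: Mapping[str, float] | None = None,
    label_rule_tau: float | None = None,
    noise: float | None = None,
    seed: int = 0,
    with_hydro: bool = True,
    spec: PhantomSpec | None = None,
) -> list[LabeledCase]:
    """Generate ``n`` labeled cases from the phantom atlas pair.

    Each case draws its injured set on the structural scheme (each ROI
    independently with its prevalence; redrawn if empty), grows one
    connected lesion through those ROIs, and extracts both scheme QFVs —
    arterial involvement then emerges from the lesion geometry, as it does
    clinically. Every ROI of both schemes is labeled by
    ``true overlap >= tau``, flipped with probability ``noise``. With
    ``with_hydro``, an ADC phantom with a per-case ventricle scale supplies
    the ventricular ratios, and scale > 1.25 (noise-flipped) defines the
    hydrocephalus label. Case provenance (drawn targets, seeds, scale) is
    kept in each case's ``meta``.
    """
    if n < 20:
        raise ValueError("cohort size must be at least 20")
    spec = spec or PhantomSpec()
    tau = spec.label_rule_tau if label_rule_tau is None else label_rule_tau
    noise = spec.label_noise if noise is None else noise
    rng = np.random.default_rng(seed)

    struct_names = atlas.structural.roi_names
    if prevalence is None:
        prevalence = {r: spec.prevalence for r in struct_names}
    else:
        prevalence = {
            r: prevalence.get(f"structural:{r}", prevalence.get(r, 0.0))
            for r in struct_names
        }

    strips = None
    if with_hydro:
        from .hydro import build_ventricle_strips

        strips = build_ventricle_strips(atlas.ventricles)

    cases: list[LabeledCase] = []
    for _ in range(n):
        crng = np.random.default_rng(int(rng.integers(0, 2**31 - 1)))
        targets: dict[str, float] = {}
        while not targets:
            targets = {
                r: float(
                    crng.uniform(spec.lesion_fraction_low, spec.lesion_fraction_high)
                )
                for r in struct_names
                if crng.random() < prevalence[r]
            }
        mask = make_lesion(
            atlas.structural,
            targets,
            tol=spec.overlap_tol,
            seed=int(crng.integers(0, 2**31 - 1)),
        )
        q_art = extract_qfv(mask, atlas.arterial)
        q_struct = extract_qfv(mask, atlas.structural)

        labels: dict[str, int] = {}
        for q in (q_art, q_struct):
            for r, f in q.fractions.items():
                y = int(f >= tau)
                if crng.random() < noise:
                    y = 1 - y
                labels[f"{q.scheme}:{r}"] = y

        hydro = None
        hydrocephalus = None
        scale = None
        if with_hydro:
            from .hydro import hydro_features

            scale = float(crng.uniform(0.7, 1.6))
            adc = make_adc_phantom(
                atlas.ventricles,
                ventricle_scale=scale,
                seed=int(crng.integers(0, 2**31 - 1)),
            )
            hydro = hydro_features(adc, strips)
            hydrocephalus = int(scale > 1.25)
            if crng.random() < noise:
                hydrocephalus = 1 - hydrocephalus

        case = make_case(
            [q_art, q_struct], labels=labels, hydro=hydro,
            hydrocephalus=hydrocephalus,
        )
        case.meta = {"targets": targets, "ventricle_scale": scale}
        cases.append(case)
    return cases


def make_adc_phantom(
    ventricles: LabeledVolume,
    ventricle_scale: float = 1.0,
    seed: int = 0,
    csf_mean: float = 0.003,
    csf_sd: float = 0.0003,
    tissue_mean: float = 0.0008,
    tissue_sd: float = 0.0001,
) -> ScalarVolume:
    """ADC map with CSF-like intensities in a (scaled) ventricular zone and
    parenchyma-like intensities elsewhere, truncated positive.

    ``ventricle_scale`` > 1 dilates the CSF zone (ventricular enlargement),
    < 1 erodes it (compression); 1.0 reproduces the atlas ventricles.
    """
    if ventricle_scale <= 0:
        raise ValueError("ventricle_scale must be positive")
    rng = np.random.default_rng(seed)
    union = ventricles.labels > 0
    zone = union
    layers_per_unit = 4  # voxel layers of zone change per unit of scale
    delta = int(round(abs(ventricle_scale - 1.0) * layers_per_unit))
    if delta > 0:
        op = ndimage.binary_dilation if ventricle_scale > 1 else ndimage.binary_erosion
        zone = op(union, iterations=delta)
    values = rng.normal(tissue_mean, tissue_sd, size=ventricles.grid.shape)
    values[zone] = rng.normal(csf_mean, csf_sd, size=int(zone.sum()))
    values = np.clip(values, 1e-6, None)
    return ScalarVolume(grid=ventricles.grid, values=values, units="mm^2/s")


def make_aspects_phantom(
    shape: tuple[int, int, int] = (40, 40, 40), seed: int = 0
) -> LabeledVolume:
    """A ten-region parcellation carrying the ASPECTS scheme names, for
    exercising the MCA-ASPECTS computation (synthetic stand-in geometry, not
    a clinical ASPECTS atlas)."""
    from .report import ASPECTS_REGIONS

    rng = np.random.default_rng(seed)
    grid = _centered_grid(shape)
    brain = _ellipsoid_brain(shape)
    coords = np.argwhere(brain)
    chosen = rng.choice(len(coords), size=10, replace=False)
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    best = np.full(shape, np.inf)
    labels = np.zeros(shape, dtype=np.int32)
    for label, idx in enumerate(chosen, start=1):
        s = coords[idx]
        d2 = (ii - s[0]) ** 2 + (jj - s[1]) ** 2 + (kk - s[2]) ** 2
        closer = d2 < best
        labels[closer] = label
        best = np.minimum(best, d2)
    labels[~brain] = 0
    table = [LabelRow(i + 1, name, "aspects") for i, name in enumerate(ASPECTS_REGIONS)]
    return LabeledVolume(grid=grid, labels=labels, table=table)
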