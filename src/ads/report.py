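"""Structured radiological report: hemisphere, territories, structures,
hydrocephalus, MCA-ASPECTS, and the fixed-template prose.

Positive territory predictions are asserted outright when their probability
reaches the confidence band (default 0.70) and qualified with "possibly"
below it. Structures are listed in atlas-table order. ASPECTS is 10 minus
the number of the ten MCA regions whose injury fraction reaches tau.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

from .core_io import BinaryLesionMask
from .models import RegionPredictionSet
from .qfv import QFVector

__all__ = [
    "RadiologyReport",
    "ASPECTS_REGIONS",
    "TERRITORY_PHRASES",
    "STRUCTURE_PHRASES",
    "determine_hemisphere",
    "compute_aspects",
    "render_report",
    "parse_report_text",
]

#: the ten MCA-territory regions scored by ASPECTS
ASPECTS_REGIONS = (
    "caudate",
    "lentiform",
    "internal capsule",
    "insular ribbon",
    "M1",
    "M2",
    "M3",
    "M4",
    "M5",
    "M6",
)

#: arterial-territory display phrases: (asserted form, "possibly" form)
TERRITORY_PHRASES: dict[str, tuple[str, str]] = {
    "ACA": ("the anterior cerebral artery", "Anterior Cerebral"),
    "MCA": ("the middle cerebral artery", "Middle Cerebral"),
    "PCA": ("the posterior cerebral artery", "Posterior Cerebral"),
    "cerebellar": ("the cerebellar arteries", "Cerebellar"),
    "basilar": ("the basilar artery", "Basilar"),
    "Lat. Lenticul.": ("the lateral lenticulostriate arteries", "Lateral Lenticulostriate"),
    "Chor&Thal.Perf": (
        "the choroidal and thalamoperforating arteries",
        "Choroidal and Thalamoperforating",
    ),
    "watershed": ("the watershed zone", "Watershed"),
}

#: structural display names where the atlas-table short name differs
STRUCTURE_PHRASES: dict[str, str] = {
    "deep wm": "deep white matter",
    "int. capsule": "internal capsule",
}


@dataclass
class RadiologyReport:
    hemisphere: str
    volume_ml: float
    territories_asserted: list[str]
    territories_possible: list[str]
    structures: list[str]
    hydrocephalus: bool
    aspects: int | None
    text: str = ""

    def __post_init__(self) -> None:
        if self.hemisphere not in ("left", "right", "bilateral"):
            raise ValueError(f"bad hemisphere {self.hemisphere!r}")
        if self.aspects is not None and not 0 <= self.aspects <= 10:
            raise ValueError("ASPECTS must lie in [0, 10]")
        if set(self.territories_asserted) & set(self.territories_possible):
            raise ValueError("a territory cannot be both asserted and possible")
        if not self.text:
            self.text = _render_text(self)

    def to_dict(self) -> dict:
        return {
            "hemisphere": self.hemisphere,
            "volume_ml": self.volume_ml,
            "territories_asserted": list(self.territories_asserted),
            "territories_possible": list(self.territories_possible),
            "structures": list(self.structures),
            "hydrocephalus": self.hydrocephalus,
            "aspects": self.aspects,
            "text": self.text,
        }


def determine_hemisphere(
    mask: BinaryLesionMask, bilateral_fraction: float = 0.10
) -> str:
    """Lesioned hemisphere from the world-x sign of the lesion voxels.

    Returns ``bilateral`` when the minor side holds at least
    ``bilateral_fraction`` of the lesion voxels, otherwise the major side.
    World x > 0 is the right hemisphere (RAS); exact-midline voxels count to
    neither side.
    """
    if mask.n_voxels == 0:
        raise ValueError("empty lesion mask")
    wx = mask.grid.world_x()[mask.as_bool()]
    n_right = int((wx > 0).sum())
    n_left = int((wx < 0).sum())
    total = n_right + n_left
    if total == 0:
        return "bilateral"  # all voxels exactly on the midline
    minor = min(n_left, n_right) / total
    if minor >= bilateral_fraction:
        return "bilateral"
    return "right" if n_right > n_left else "left"


def compute_aspects(qfv_aspects: QFVector, tau: float = 0.05) -> int:
    """MCA-ASPECTS: 10 minus the number of ASPECTS regions with injury
    fraction >= ``tau``."""
    regions = set(qfv_aspects.fractions)
    if len(qfv_aspects.fractions) != 10 or regions != set(ASPECTS_REGIONS):
        raise ValueError(
            "ASPECTS QFV must cover exactly the 10 regions "
            f"{ASPECTS_REGIONS}; got {sorted(regions)}"
        )
    involved = sum(1 for f in qfv_aspects.fractions.values() if f >= tau)
    return 10 - involved


def _oxford_join(items: Sequence[str]) -> str:
    items = list(items)
    if len(items) == 1:
        return items[0]
    if len(items) == 2:
        return f"{items[0]} and {items[1]}"
    return ", ".join(items[:-1]) + ", and " + items[-1]


def _territory_clause(asserted: Sequence[str], possible: Sequence[str]) -> str:
    parts = []
    if asserted:
        names = [TERRITORY_PHRASES.get(t, (t, t))[0] for t in asserted]
        parts.append("in the territory of " + " and ".join(names))
    if possible:
        names = [TERRITORY_PHRASES.get(t, (t, t))[1] for t in possible]
        poss = "possibly " + " and ".join(names)
        parts.append(poss if asserted else "possibly in the territory of "
                     + " and ".join(names))
    if not parts:
        return ""
    return ", " + " and ".join(parts)


def _render_text(report: RadiologyReport) -> str:
    side = (
        "within both brain hemispheres"
        if report.hemisphere == "bilateral"
        else f"within the {report.hemisphere} brain hemisphere"
    )
    text = (
        f"Area of restricted diffusion {side}, "
        f"with {report.volume_ml:.3f} ml"
        f"{_territory_clause(report.territories_asserted, report.territories_possible)}."
    )
    if report.structures:
        names = [STRUCTURE_PHRASES.get(s, s) for s in report.structures]
        noun = "region" if len(names) == 1 else "regions"
        text += f" The area involves the following brain {noun}: {_oxford_join(names)}."
    if report.hydrocephalus:
        text += " There is hydrocephalus."
    else:
        text += " There is no hydrocephalus."
    if report.aspects is not None:
        text += f" The predicted MCA-ASPECTS is {report.aspects}."
    return text


def render_report(
    preds_arterial: RegionPredictionSet | Mapping[str, tuple[int, float]],
    preds_structural: RegionPredictionSet | Mapping[str, tuple[int, float]],
    hydro: bool,
    volume_ml: float,
    hemisphere: str,
    aspects: int | None = None,
    possible_band: float = 0.70,
) -> RadiologyReport:
    """Assemble the structured report and its deterministic prose.

    ``preds_*`` map ROI name -> (label, probability), or are prediction sets
    whose arterial/structural scheme is extracted. Positive territories with
    probability >= ``possible_band`` are asserted; the rest are "possibly".
    """
    art = (
        preds_arterial.for_scheme("arterial")
        if isinstance(preds_arterial, RegionPredictionSet)
        else dict(preds_arterial)
    )
    struct = (
        preds_structural.for_scheme("structural")
        if isinstance(preds_structural, RegionPredictionSet)
        else dict(preds_structural)
    )
    asserted = [t for t, (lab, p) in art.items() if lab == 1 and p >= possible_band]
    possible = [t for t, (lab, p) in art.items() if lab == 1 and p < possible_band]
    structures = [s for s, (lab, _p) in struct.items() if lab == 1]
    return RadiologyReport(
        hemisphere=hemisphere,
        volume_ml=float(volume_ml),
        territories_asserted=asserted,
        territories_possible=possible,
        structures=structures,
        hydrocephalus=bool(hydro),
        aspects=aspects,
    )


# ---------------------------------------------------------------------------
# Parsing (round-trip check of the fixed template)
# ---------------------------------------------------------------------------

_HEMI_RE = re.compile(
    r"^Area of restricted diffusion within (?:the (left|right) brain hemisphere|"
    r"both brain hemispheres()), with ([0-9.]+) ml(.*?)\."
    r"(?: The area involves the following brain regions?: (.*?)\.)?"
    r" There is (no )?hydrocephalus\."
    r"(?: The predicted MCA-ASPECTS is (\d+)\.)?$"
)

_REVERSE_TERRITORY = {
    phrase: name for name, (phrase, _) in TERRITORY_PHRASES.items()
} | {poss: name for name, (_, poss) in TERRITORY_PHRASES.items()}
_REVERSE_STRUCTURE = {v: k for k, v in STRUCTURE_PHRASES.items()}


def _segment(chunk: str, vocab: set[str]) -> list[str] | None:
    """Split a chunk on " and " while keeping known multi-word phrases
    (some display names contain "and" themselves) intact."""
    if not chunk:
        return []
    if chunk in vocab:
        return [chunk]
    parts = chunk.split(" and ")
    if len(parts) == 1:
        return None
    for i in range(1, len(parts)):
        left = " and ".join(parts[:i])
        if left in vocab or " and " not in left:
            rest = _segment(" and ".join(parts[i:]), vocab)
            if rest is not None:
                return [left] + rest
    return None


def _split_names(joined: str, vocab: set[str] = frozenset()) -> list[str]:
    joined = joined.replace(", and ", ", ")
    parts: list[str] = []
    for chunk in joined.split(", "):
        seg = _segment(chunk, set(vocab))
        parts.extend(seg if seg is not None else [p for p in chunk.split(" and ") if p])
    return parts


def parse_report_text(text: str) -> RadiologyReport:
    """Invert the fixed template back into structured fields."""
    m = _HEMI_RE.match(text)
    if not m:
        raise ValueError("text does not match the report template")
    side, both, vol, terr_clause, structs, no_hydro, aspects = m.groups()
    hemisphere = "bilateral" if both is not None else side
    terr_vocab = set(_REVERSE_TERRITORY)
    struct_vocab = set(_REVERSE_STRUCTURE)
    asserted: list[str] = []
    possible: list[str] = []
    clause = terr_clause.strip()
    if clause.startswith(","):
        clause = clause[1:].strip()
    if clause:
        if clause.startswith("possibly in the territory of "):
            possible = _split_names(
                clause[len("possibly in the territory of "):], terr_vocab
            )
        else:
            head, _, tail = clause.partition(" and possibly ")
            if head.startswith("in the territory of "):
                asserted = _split_names(head[len("in the territory of "):], terr_vocab)
            if tail:
                possible = _split_names(tail, terr_vocab)
    return RadiologyReport(
        hemisphere=hemisphere,
        volume_ml=float(vol),
        territories_asserted=[_REVERSE_TERRITORY.get(t, t) for t in asserted],
        territories_possible=[_REVERSE_TERRITORY.get(t, t) for t in possible],
        structures=[
            _REVERSE_STRUCTURE.get(s, s)
            for s in (_split_names(structs, struct_vocab) if structs else [])
        ],
        hydrocephalus=no_hydro is None,
        aspects=int(aspects) if aspects is not None else None,
    )
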