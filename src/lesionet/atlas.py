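"""ROI atlas: named brain regions with hemisphere labels and bilateral pairing.

The atlas fixes the region index set over which all measurement tables and
correlation matrices are defined, and resolves laterality: ``lesion_side``
designates the hemisphere that counts as "ipsilateral" throughout the
pipeline (default right — the lesion model injects blood into the right
striatum).

The default atlas has 9 bilateral pairs (18 regions): striatum, thalamus,
hippocampus, amygdala, and frontal, parietal, temporal, occipital and
cingulate cortices.  Region naming convention is ``<pair>_l`` / ``<pair>_r``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ValidationError

HEMISPHERES = ("left", "right", "midline")

_DEFAULT_PAIRS = (
    "striatum",
    "thalamus",
    "hippocampus",
    "amygdala",
    "frontal",
    "parietal",
    "temporal",
    "occipital",
    "cingulate",
)


@dataclass(frozen=True)
class Region:
    name: str
    hemisphere: str  # left | right | midline
    pair_id: str | None = None


@dataclass
class RoiAtlas:
    """Ordered region list plus which hemisphere is ipsilateral to the lesion."""

    regions: list[Region] = field(default_factory=list)
    lesion_side: str = "right"

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.regions]

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def pairs(self) -> list[tuple[str, str, str]]:
        """Bilateral pairs as ``(pair_id, ipsilateral_name, contralateral_name)``.

        Order follows first appearance of each pair_id in the region list.
        Midline/unpaired regions are skipped.
        """
        by_pair: dict[str, dict[str, str]] = {}
        order: list[str] = []
        for r in self.regions:
            if r.pair_id is None:
                continue
            if r.pair_id not in by_pair:
                by_pair[r.pair_id] = {}
                order.append(r.pair_id)
            by_pair[r.pair_id][r.hemisphere] = r.name
        ipsi = self.lesion_side
        contra = "left" if ipsi == "right" else "right"
        out = []
        for pid in order:
            sides = by_pair[pid]
            if ipsi in sides and contra in sides:
                out.append((pid, sides[ipsi], sides[contra]))
        return out

    def with_lesion_side(self, side: str) -> "RoiAtlas":
        if side not in ("left", "right"):
            raise ValidationError(f"lesion_side must be 'left' or 'right', got {side!r}")
        return RoiAtlas(regions=list(self.regions), lesion_side=side)


def validate_atlas(atlas: RoiAtlas) -> list[str]:
    """Return one diagnostic string per invariant violation (empty = valid)."""
    diags: list[str] = []
    seen: dict[str, int] = {}
    for r in atlas.regions:
        seen[r.name] = seen.get(r.name, 0) + 1
    for name, count in seen.items():
        if count > 1:
            diags.append(f"duplicate region name {name!r} ({count} occurrences)")
    for r in atlas.regions:
        if r.hemisphere not in HEMISPHERES:
            diags.append(f"region {r.name!r}: unknown hemisphere {r.hemisphere!r}")
    if atlas.lesion_side not in ("left", "right"):
        diags.append(f"lesion_side must be 'left' or 'right', got {atlas.lesion_side!r}")

    by_pair: dict[str, list[Region]] = {}
    for r in atlas.regions:
        if r.pair_id is not None:
            by_pair.setdefault(r.pair_id, []).append(r)
    for pid, members in by_pair.items():
        if len(members) != 2:
            diags.append(
                f"pair {pid!r} has {len(members)} member(s), expected exactly 2"
            )
            continue
        hemis = sorted(m.hemisphere for m in members)
        if hemis != ["left", "right"]:
            diags.append(
                f"pair {pid!r} members must be one left + one right, got {hemis}"
            )
    return diags


def default_atlas(lesion_side: str = "right") -> RoiAtlas:
    """The built-in 18-region bilateral atlas (9 pairs, left/right)."""
    regions = []
    for pid in _DEFAULT_PAIRS:
        regions.append(Region(f"{pid}_l", "left", pid))
        regions.append(Region(f"{pid}_r", "right", pid))
    return RoiAtlas(regions=regions, lesion_side=lesion_side)


def read_atlas(path: str | Path) -> RoiAtlas:
    """Read an atlas from YAML (``regions:`` list + ``lesion_side``)."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "regions" not in doc:
        raise ValidationError(f"atlas file {path}: expected a mapping with a 'regions' list")
    regions = [
        Region(
            name=str(entry["name"]),
            hemisphere=str(entry["hemisphere"]),
            pair_id=(None if entry.get("pair_id") in (None, "") else str(entry["pair_id"])),
        )
        for entry in doc["regions"]
    ]
    atlas = RoiAtlas(regions=regions, lesion_side=str(doc.get("lesion_side", "right")))
    diags = validate_atlas(atlas)
    if diags:
        raise ValidationError(f"atlas file {path} invalid: " + "; ".join(diags))
    return atlas


def write_atlas(atlas: RoiAtlas, path: str | Path) -> None:
    doc = {
        "lesion_side": atlas.lesion_side,
        "regions": [
            {"name": r.name, "hemisphere": r.hemisphere, "pair_id": r.pair_id}
            for r in atlas.regions
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
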