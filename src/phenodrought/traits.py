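"""Classification of image-derived trait names.

Image-analysis pipelines for plant phenotyping emit hundreds of traits
whose dotted names encode how each was measured: the camera (visible
light, static fluorescence, near-infrared, or a multi-camera composite),
the trait category (color-related, texture, geometric), the summary
statistic (first-order value, standard deviation, skewness), the color
scale (RGB, HSV, L*a*b*), and the viewpoint (side, top, or combined).
:func:`classify_trait` recovers this classification from the name alone,
and :func:`summarize_classification` cross-tabulates acceptance of traits
along each of the five axes.

The token grammar is inferred from the published selected-trait
catalogue bundled as :data:`TRAIT_CATALOGUE`; names are normalized
(lower-cased, whitespace stripped) first because printed names carry
incidental spaces.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

CAMERAS = ("VIS", "FLUOR", "NIR", "MULTI")
CATEGORIES = ("color", "texture", "geometric")
STATISTICS = ("first-order", "stddev", "skewness")
COLOR_SCALES = ("none", "RGB", "HSV", "LAB")
VIEWPOINTS = ("side", "top", "combined")


class TraitClassificationError(ValueError):
    """A trait name matched no known camera token."""


@dataclass(frozen=True)
class TraitMetadata:
    trait_id: str
    name: str
    camera: str
    category: str
    statistic: str
    color_scale: str
    viewpoint: str


def normalize_trait_name(name: str) -> str:
    """Lower-case and strip all whitespace (printed names wrap with spaces)."""
    return "".join(name.split()).lower()


def classify_trait(name: str, trait_id: str | None = None) -> TraitMetadata:
    """Classify one trait from its dotted name.

    Raises :class:`TraitClassificationError` if the name carries no
    camera token; all other axes fall back to their default level
    (first-order / no color scale / combined view).
    """
    if not name or not name.strip():
        raise TraitClassificationError("empty trait name")
    norm = normalize_trait_name(name)
    tokens = [t for t in norm.split(".") if t]

    if "multi.camera" in norm:
        camera = "MULTI"
    elif "fluorescence" in norm:
        camera = "FLUOR"
    elif "visible.light" in norm:
        camera = "VIS"
    elif "nir" in tokens:
        camera = "NIR"
    else:
        raise TraitClassificationError(f"no camera token in trait name {name!r}")

    if "color.related" in norm:
        category = "color"
    elif "texture.trait" in norm:
        category = "texture"
    else:
        category = "geometric"

    if "stddev" in tokens or "std" in tokens:
        statistic = "stddev"
    elif "skewness" in tokens:
        statistic = "skewness"
    else:
        statistic = "first-order"

    color_scale = {"rgb": "RGB", "hsv": "HSV", "lab": "LAB"}.get(tokens[0], "none")

    if "side.view" in norm:
        viewpoint = "side"
    elif "top.view" in norm:
        viewpoint = "top"
    else:
        viewpoint = "combined"

    return TraitMetadata(
        trait_id=trait_id if trait_id is not None else norm,
        name=name,
        camera=camera,
        category=category,
        statistic=statistic,
        color_scale=color_scale,
        viewpoint=viewpoint,
    )


_AXES = {
    "camera": ("camera", CAMERAS),
    "category": ("category", CATEGORIES),
    "statistic": ("statistic", STATISTICS),
    "color_scale": ("color_scale", COLOR_SCALES),
    "viewpoint": ("viewpoint", VIEWPOINTS),
}


def summarize_classification(metadata: list[TraitMetadata],
                             accepted: set[str]) -> pd.DataFrame:
    """Acceptance bookkeeping along the five classification axes.

    Returns one row per (axis, level) with counts of not-accepted and
    accepted traits, percent accepted (2 decimals), and the level total,
    plus a ``Total`` row per axis.  ``accepted`` must be a subset of the
    classified trait ids.
    """
    ids = {m.trait_id for m in metadata}
    stray = accepted - ids
    if stray:
        raise ValueError(f"accepted ids not present in metadata: {sorted(stray)[:10]}")
    rows = []
    n_total = len(metadata)
    n_acc_total = sum(m.trait_id in accepted for m in metadata)
    for axis, (attr, levels) in _AXES.items():
        for level in levels:
            members = [m for m in metadata if getattr(m, attr) == level]
            if not members:
                continue
            acc = sum(m.trait_id in accepted for m in members)
            rows.append((axis, level, len(members) - acc, acc,
                         round(100.0 * acc / len(members), 2), len(members)))
        if metadata:
            rows.append((axis, "Total", n_total - n_acc_total, n_acc_total,
                         round(100.0 * n_acc_total / n_total, 2), n_total))
    return pd.DataFrame(
        rows, columns=["axis", "level", "not_accepted", "accepted",
                       "pct_accepted", "total"]
    )


#: Published catalogue of selected image traits: (trait number, printed name
#: with its incidental line-wrap spaces, selected for the main-spike complex,
#: selected for thousand grain weight).
TRAIT_CATALOGUE: tuple[tuple[int, str, bool, bool], ...] = (
    (16, "hull.circularity.geometry.trait.based. on.fluorescence.side.view.", True, True),
    (39, "area.geometry.trait.based.on. visible.light.side.view.px.2.", False, True),
    (75, "hull.pc2.geometry.trait.based.on. visible.light.side.view.px.", True, True),
    (104, "hsv.h.mean.color.related.trait.based. on.fluorescence.side.view.", True, True),
    (115, "hsv.v.mean.color.related.trait.based. on.fluorescence.side.view.", False, True),
    (124, "intensity.phenol.mean.color.related. trait.based.on.fluorescence.side.view.", True, False),
    (135, "lab.b.stddev.color.related.trait.based.on. fluorescence.side.view.", False, True),
    (139, "hsv.h.yellow2green.color.related.trait. based.on.visible.light.side.view.", True, False),
    (141, "hsv.h.skewness.color.related.trait. based.on.visible.light.side.view.", True, False),
    (143, "hsv.h.mean.color.related.trait.based. on.visible.light.side.view.", True, False),
    (144, "hsv.h.brown2green.color.related.trait. based.on.visible.light.side.view.", True, True),
    (150, "lab.a.stddev.color.related.trait.based. on.visible.light.side.view.", True, False),
    (154, "hsv.v.skewness.color.related.trait. based.on.visible.light.side.view.", True, False),
    (157, "rgb.red.mean.color.related.trait. based.on.visible.light.side.view.", True, False),
    (166, "rgb.g.std.texture.trait.based.on. fluorescence.side.view.", False, True),
    (174, "rgb.r.std.texture.trait.based.on. fluorescence.side.view.", True, False),
    (194, "hull.area.zoom.corrected.geometry.trait. based.on.fluorescence.top.view.mm.2.", True, False),
    (256, "hull.compactness.16.geometry.trait. based.on.visible.light.top.view.", True, True),
    (261, "leaf.length.sum.geometry.trait. based.on.visible.light.top.view.px.", True, False),
    (269, "hull.pc2.geometry.trait.based.on. visible.light.top.view.px.", True, False),
    (316, "ndvi.color.related.trait.based.on. multi.camera.top.view.", True, False),
    (320, "hsv.v.mean.color.related.trait. based.on.visible.light.top.view.", True, False),
    (321, "hsv.s.stddev.color.related.trait. based.on.visible.light.top.view.", False, True),
    (325, "hsv.h.stddev.color.related.trait. based.on.visible.light.top.view.", False, True),
    (330, "lab.b.stddev.color.related.trait. based.on.visible.light.top.view.", True, False),
    (337, "rgb.red.mean.color.related.trait. based.on.visible.light.top.view.", True, False),
    (353, "rgb.b.std.texture.trait.based.on. visible.light.top.view.", True, False),
)


def catalogue_metadata() -> list[TraitMetadata]:
    """Classify every name in the bundled selected-trait catalogue."""
    return [classify_trait(name, trait_id=str(no))
            for no, name, _, _ in TRAIT_CATALOGUE]
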