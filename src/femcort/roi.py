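"""ROI numbering convention for the 31 cortical measurement sites.

The proximal femur is sampled at eight cross-sections: S1-S3 through the
femoral neck (subcephalic, middle, bottom) and S4-S8 through the shaft
(20 mm above the lesser-trochanter upper edge, the upper edge, the vertex,
the lower edge, and 20 mm below the vertex).  Each neck section contributes
four wall sites (upper, lower, anterior, posterior); each shaft section
contributes four (medial, anterior, lateral, posterior) except S4, whose
medial wall is skipped because it merges with the femoral neck/head.

The resulting 31 sites are numbered:

========  ================  =======================================
section   ROI ids           wall order
========  ================  =======================================
S1        1-4               upper, lower, anterior, posterior
S2        5-8               upper, lower, anterior, posterior
S3        9-12              upper, lower, anterior, posterior
S4        13-15             anterior, lateral, posterior
S5        16-19             medial, anterior, lateral, posterior
S6        20-23             medial, anterior, lateral, posterior
S7        24-27             medial, anterior, lateral, posterior
S8        28-31             medial, anterior, lateral, posterior
========  ================  =======================================

This ordering puts ROI 14 on the lateral cortex of S4 (the vastus
lateralis ridge), ROI 21 on the anterior wall at the lesser-trochanter
vertex, and the thick medial walls at ROIs 16 and 28 -- the anatomical
anchors of the protocol.
"""

from __future__ import annotations

NECK_SECTIONS: tuple[str, ...] = ("S1", "S2", "S3")
SHAFT_SECTIONS: tuple[str, ...] = ("S4", "S5", "S6", "S7", "S8")
ALL_SECTIONS: tuple[str, ...] = NECK_SECTIONS + SHAFT_SECTIONS

NECK_WALLS: tuple[str, ...] = ("upper", "lower", "anterior", "posterior")
SHAFT_WALLS: tuple[str, ...] = ("medial", "anterior", "lateral", "posterior")


def _build_table() -> list[tuple[int, str, str]]:
    rows: list[tuple[int, str, str]] = []
    rid = 1
    for sec in NECK_SECTIONS:
        for wall in NECK_WALLS:
            rows.append((rid, sec, wall))
            rid += 1
    for sec in SHAFT_SECTIONS:
        for wall in SHAFT_WALLS:
            if sec == "S4" and wall == "medial":
                continue
            rows.append((rid, sec, wall))
            rid += 1
    assert rid == 32
    return rows


#: (roi_id, section, wall) for all 31 sites, in id order.
ROI_TABLE: tuple[tuple[int, str, str], ...] = tuple(_build_table())

#: roi_id -> (section, wall)
ROI_TO_SITE: dict[int, tuple[str, str]] = {r: (s, w) for r, s, w in ROI_TABLE}

#: (section, wall) -> roi_id
SITE_TO_ROI: dict[tuple[str, str], int] = {(s, w): r for r, s, w in ROI_TABLE}


def walls_of(section: str) -> tuple[str, ...]:
    """Measured walls of a section, in ROI-id order."""
    if section in NECK_SECTIONS:
        return NECK_WALLS
    if section == "S4":
        return ("anterior", "lateral", "posterior")
    if section in SHAFT_SECTIONS:
        return SHAFT_WALLS
    raise ValueError(f"unknown section {section!r}")
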