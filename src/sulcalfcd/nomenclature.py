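"""Sulcal nomenclature of the central region.

The analysis is restricted to the 13 sulci surrounding the central sulcus
(primary sensorimotor cortex), following the BrainVisa naming scheme: the
central sulcus itself, its postcentral and precentral neighbours, and the
three small ramifications of the central sulcus (central sylvian sulcus,
paracentral lobule sulcus, paracentral sulcus).
"""

from __future__ import annotations

# Ordered from the most stable sulcus across individuals (the central
# sulcus) to the most variable (the central sylvian sulcus).  This ordering
# doubles as the variability rank used by the synthetic template.
CENTRAL_REGION_LABELS: tuple[str, ...] = (
    "S.C.",              # central sulcus
    "S.Po.C.sup",        # superior postcentral sulcus
    "S.Pe.C.sup",        # superior precentral sulcus
    "S.Pe.C.inf",        # inferior precentral sulcus
    "S.Pe.C.median",     # median precentral sulcus
    "S.Pe.C.marginal",   # marginal precentral sulcus
    "S.Pe.C.inter",      # intermediate precentral sulcus
    "S.F.median",        # median frontal sulcus
    "F.I.P.Po.C.inf",    # inferior postcentral ramus of the intraparietal sulcus
    "F.C.L.r.retroC.tr", # retrocentral transverse ramus of the lateral fissure
    "S.p.C",             # paracentral sulcus
    "S.C.LPC",           # paracentral lobule sulcus
    "S.C.sylvian",       # central sylvian sulcus
)

BACKGROUND = "background"

HEMISPHERES = ("left", "right")

_CANONICAL = {name.rstrip(".").lower(): name for name in CENTRAL_REGION_LABELS}


def is_central_region(label: str) -> bool:
    return label in CENTRAL_REGION_LABELS


def canonical_label(name: str) -> str:
    """Normalise a sulcus name to the canonical nomenclature spelling.

    Annotation tables in the literature vary in trailing periods and case
    (e.g. ``S.C.LPC.`` vs ``S.C.LPC``); this maps any such variant onto the
    canonical spelling and raises ``ValueError`` for names outside the
    central-region nomenclature.
    """
    key = name.strip().rstrip(".").lower()
    if key in _CANONICAL:
        return _CANONICAL[key]
    raise ValueError(f"unknown central-region sulcus name: {name!r}")
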