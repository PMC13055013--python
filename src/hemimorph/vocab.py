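"""Region vocabularies, measure names, and region-name canonicalization.

The cortical vocabulary is the standard 34-parcel Desikan-Killiany list in
``aparc.stats`` row order; subcortical and gross vocabularies are fixed
9- and 3-name lists. Canonical region names are lowercase with no
separators (gross measures keep their conventional uppercase acronyms).
"""

from __future__ import annotations

import re

# measures
CXT = "CxT"
CSA = "CSA"
CV = "CV"
SUBCORTICAL_VOL = "subcortical_vol"
GROSS_VOL = "gross_vol"

MEASURES = (CXT, CSA, CV, SUBCORTICAL_VOL, GROSS_VOL)
CORTICAL_MEASURES = (CXT, CSA, CV)

CORTICAL_34 = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "parahippocampal",
    "paracentral",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "frontalpole",
    "temporalpole",
    "transversetemporal",
    "insula",
)

SUBCORTICAL_9 = (
    "accumbens",
    "amygdala",
    "caudate",
    "cerebellum",
    "hippocampus",
    "pallidum",
    "putamen",
    "thalamus",
    "ventraldiencephalon",
)

GROSS_3 = ("LV", "GM", "WM")

assert len(CORTICAL_34) == 34
assert len(SUBCORTICAL_9) == 9
assert len(GROSS_3) == 3

# Aliases map *flattened* spellings (lowercase, alphanumerics only, any
# Left-/Right-/lh/rh prefix stripped) onto canonical names. FreeSurfer aseg
# structure names land here after flattening.
_ALIASES = {
    "accumbensarea": "accumbens",
    "nucleusaccumbens": "accumbens",
    "thalamusproper": "thalamus",
    "ventraldc": "ventraldiencephalon",
    "cerebellumcortex": "cerebellum",
    "lateralventricle": "LV",
    "cerebralcortex": "GM",
    "cerebralwhitematter": "WM",
    "lv": "LV",
    "gm": "GM",
    "wm": "WM",
}

_PREFIX = re.compile(r"^(left-|right-|lh[-_.]|rh[-_.]|lh|rh)", re.IGNORECASE)
_NONALNUM = re.compile(r"[^a-z0-9]+")


class UnknownRegionError(ValueError):
    """A region name outside the vocabulary of its measure."""


def flatten_name(name: str) -> str:
    """Strip hemisphere prefixes/separators and lowercase."""
    s = _PREFIX.sub("", name.strip())
    return _NONALNUM.sub("", s.lower())


def vocabulary_for(measure: str) -> tuple[str, ...]:
    if measure in CORTICAL_MEASURES:
        return CORTICAL_34
    if measure == SUBCORTICAL_VOL:
        return SUBCORTICAL_9
    if measure == GROSS_VOL:
        return GROSS_3
    raise ValueError(f"unknown measure {measure!r}")


def canonical_region(name: str, measure: str) -> str:
    """Map ``name`` onto the canonical vocabulary of ``measure``.

    Raises :class:`UnknownRegionError` if the flattened name (after alias
    resolution) is not in the measure's vocabulary.
    """
    flat = flatten_name(name)
    flat = _ALIASES.get(flat, flat)
    vocab = vocabulary_for(measure)
    if flat in vocab:
        return flat
    raise UnknownRegionError(f"region {name!r} is not valid for measure {measure!r}")


def try_canonical_region(name: str) -> str | None:
    """Resolve a name against any vocabulary, or None if unknown anywhere."""
    flat = flatten_name(name)
    flat = _ALIASES.get(flat, flat)
    for vocab in (CORTICAL_34, SUBCORTICAL_9, GROSS_3):
        if flat in vocab:
            return flat
    return None
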