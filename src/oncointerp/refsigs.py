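"""Synthetic reference signature matrices (COSMIC-style layout).

The real COSMIC catalogues cannot be redistributed here, so this module builds a
*synthetic* stand-in reference: one probability column per signature, generated
deterministically from the signature's name as a seeded random spectrum blended
with a themed peak structure that mimics the signature's qualitative character
(e.g. the clock-like N[C>T]G peaks of SBS1, the microhomology-deletion weight of
ID6, the small-tandem-duplication weight of RS3).  All downstream computations
(NNLS refitting, refinement, HRD/MSI feature fractions) depend only on the
matrix algebra, not on the actual column values, so the synthetic reference
exercises every code path faithfully.
"""

from __future__ import annotations

import zlib

import numpy as np

from .channels import ID83_CHANNELS, SBS96_CHANNELS, SV32_CHANNELS

MSI_SIGNATURES = ("SBS6", "SBS15", "SBS20", "SBS21", "SBS26", "SBS30", "SBS44")
HRD_SBS_SIGNATURES = ("SBS3", "SBS8")
HRD_SV_SIGNATURES = ("RS3", "RS5")

SBS_SIGNATURES = ("SBS1", "SBS2", "SBS3", "SBS4", "SBS5", "SBS6", "SBS8",
                  "SBS13", "SBS15", "SBS18", "SBS20", "SBS21", "SBS26",
                  "SBS30", "SBS40", "SBS44")
ID_SIGNATURES = ("ID1", "ID2", "ID3", "ID4", "ID6", "ID8")
SV_SIGNATURES = ("RS1", "RS2", "RS3", "RS4", "RS5", "RS6")


def _seed_for(name: str) -> int:
    return zlib.crc32(name.encode()) & 0x7FFFFFFF


def _themed_mask(channels: tuple[str, ...], predicate) -> np.ndarray:
    mask = np.array([1.0 if predicate(c) else 0.0 for c in channels])
    total = mask.sum()
    return mask / total if total else mask


_SBS_THEMES = {
    "SBS1": lambda c: "[C>T]G" in c,
    "SBS2": lambda c: c.startswith("T[C>T]"),
    "SBS4": lambda c: "[C>A]" in c,
    "SBS5": lambda c: "[T>C]" in c,
    "SBS13": lambda c: c.startswith("T[C>G]"),
    "SBS18": lambda c: "[C>A]" in c and c[0] in "AG",
    # MMR/MSI-associated signatures get distinct concentrated peaks so that
    # refitting can separate them from the flat HRD-type spectra
    "SBS6": lambda c: c.startswith("G[C>T]"),
    "SBS15": lambda c: "[C>T]T" in c,
    "SBS20": lambda c: c.startswith("C[C>A]"),
    "SBS21": lambda c: "[T>C]G" in c,
    "SBS26": lambda c: c.startswith("A[T>C]"),
    "SBS30": lambda c: "[C>T]A" in c and c[0] in "AT",
    "SBS44": lambda c: "[C>T]C" in c,
}

_ID_THEMES = {
    "ID1": lambda c: c.startswith("INS.T.1.") and c.split(".")[-1] in ("4", "5+"),
    "ID2": lambda c: c.startswith("DEL.T.1.") and c.split(".")[-1] in ("5", "6+"),
    "ID3": lambda c: c.startswith("DEL.C.1.") and c.split(".")[-1] in ("1", "2"),
    "ID4": lambda c: c.startswith("DEL.repeats."),
    "ID6": lambda c: c.startswith("DEL.MH."),
    "ID8": lambda c: c.startswith("DEL.repeats.") or c == "DEL.MH.5+.1",
}

_SV_THEMES = {
    "RS1": lambda c: c.startswith("non-clustered.DUP.") and ("Mb" in c.split(".")[-1]),
    "RS2": lambda c: c.startswith("non-clustered.DEL.") and ("Mb" in c.split(".")[-1]),
    "RS3": lambda c: c.startswith("non-clustered.DUP.") and c.split(".")[-1] in ("<10kb", "10-100kb"),
    "RS4": lambda c: c.startswith("clustered.") and (c.endswith("TRA") or ".INV." in c),
    "RS5": lambda c: c.startswith("non-clustered.DEL.") and c.split(".")[-1] in ("<10kb", "10-100kb"),
    "RS6": lambda c: c.startswith("clustered."),
}

# fraction of a column's mass carried by its themed peaks
_THEME_WEIGHT = 0.65


def _column(name: str, channels: tuple[str, ...], themes: dict) -> np.ndarray:
    rng = np.random.default_rng(_seed_for(name))
    noise = rng.gamma(shape=0.6, scale=1.0, size=len(channels))
    noise /= noise.sum()
    theme = themes.get(name)
    if theme is None:
        col = noise
    else:
        col = _THEME_WEIGHT * _themed_mask(channels, theme) + (1 - _THEME_WEIGHT) * noise
    return col / col.sum()


def build_reference(sig_class: str):
    """Build the synthetic reference for one class ('SBS96', 'ID83' or 'SV32')."""
    from .signatures import SignatureReference

    if sig_class == "SBS96":
        names, channels, themes = SBS_SIGNATURES, SBS96_CHANNELS, _SBS_THEMES
    elif sig_class == "ID83":
        names, channels, themes = ID_SIGNATURES, ID83_CHANNELS, _ID_THEMES
    elif sig_class == "SV32":
        names, channels, themes = SV_SIGNATURES, SV32_CHANNELS, _SV_THEMES
    else:
        raise ValueError(f"unknown signature class {sig_class!r}")
    matrix = np.column_stack([_column(n, channels, themes) for n in names])
    return SignatureReference(sig_class=sig_class, names=list(names), matrix=matrix)


# Default per-cancer-type signature sets used as the starting point of refinement.
# Deliberately minimal: refinement is expected to add what a sample needs.
DEFAULT_SIGNATURE_SETS: dict[str, dict[str, list[str]]] = {
    "default": {"SBS96": ["SBS1", "SBS5"], "ID83": ["ID1", "ID2"],
                "SV32": ["RS1", "RS2"]},
    "lung": {"SBS96": ["SBS1", "SBS4", "SBS5", "SBS13"], "ID83": ["ID1", "ID2", "ID3"],
             "SV32": ["RS1", "RS2"]},
    # SBS3/SBS8, ID6 and RS3/RS5 are prevalent in HRD-prone tissues and are part
    # of those tissues' tailored default sets
    "breast": {"SBS96": ["SBS1", "SBS2", "SBS3", "SBS5", "SBS8", "SBS13"],
               "ID83": ["ID1", "ID2", "ID6"],
               "SV32": ["RS1", "RS2", "RS3", "RS5"]},
    "prostate": {"SBS96": ["SBS1", "SBS3", "SBS5", "SBS8"],
                 "ID83": ["ID1", "ID2", "ID6"],
                 "SV32": ["RS1", "RS2", "RS3", "RS5"]},
    "ovarian": {"SBS96": ["SBS1", "SBS3", "SBS5", "SBS8"],
                "ID83": ["ID1", "ID2", "ID6"],
                "SV32": ["RS1", "RS3", "RS5"]},
    # MSI-associated signatures are prevalent in gastrointestinal cancers and
    # are part of the stomach/colorectal tailored sets
    "colorectal": {"SBS96": ["SBS1", "SBS5", "SBS18", "SBS6", "SBS15", "SBS20",
                             "SBS21", "SBS26", "SBS44"],
                   "ID83": ["ID1", "ID2"],
                   "SV32": ["RS1", "RS2"]},
    "stomach": {"SBS96": ["SBS1", "SBS3", "SBS5", "SBS8", "SBS6", "SBS15",
                          "SBS20", "SBS21", "SBS26", "SBS44"],
                "ID83": ["ID1", "ID2", "ID6"],
                "SV32": ["RS1", "RS2", "RS3", "RS5"]},
}


def default_signature_set(cancer_type: str, sig_class: str) -> list[str]:
    table = DEFAULT_SIGNATURE_SETS.get(cancer_type, DEFAULT_SIGNATURE_SETS["default"])
    return list(table[sig_class])
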