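"""Mutation channel definitions for the three signature classes.

SBS96: pyrimidine-strand single-base substitutions, 6 substitution types x 16
trinucleotide contexts, in COSMIC order (substitution major, context lexicographic).

ID83: the COSMIC small-indel classification — 1-bp insertions/deletions in C/T
homopolymers binned by homopolymer length, longer indels binned by repeat-unit size
and repeat count, and deletions at microhomology binned by size and homology length.

SV32: {clustered, non-clustered} x {DEL, DUP, INV in five size bins, TRA}.
"""

from __future__ import annotations

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"


def _sbs96_channels() -> list[str]:
    out = []
    for sub in SUBSTITUTIONS:
        ref = sub[0]
        for five in _BASES:
            for three in _BASES:
                out.append(f"{five}[{sub}]{three}")
    return out


SBS96_CHANNELS: tuple[str, ...] = tuple(_sbs96_channels())


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def sbs96_channel(ref: str, alt: str, context: str) -> str:
    """Map a substitution with its centred 3-mer context onto an SBS96 channel.

    Purine reference bases are folded onto the pyrimidine strand by
    reverse-complementing ref, alt and context.
    """
    if len(context) != 3:
        raise ValueError(f"trinucleotide context must have length 3, got {context!r}")
    if context[1] != ref:
        raise ValueError(f"context centre {context[1]!r} does not match ref {ref!r}")
    if ref not in _BASES or alt not in _BASES or ref == alt:
        raise ValueError(f"invalid substitution {ref}>{alt}")
    if ref in "AG":
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
        context = reverse_complement(context)
    channel = f"{context[0]}[{ref}>{alt}]{context[2]}"
    if channel not in _SBS96_SET:
        raise ValueError(f"not an SBS96 channel: {channel}")
    return channel


_SBS96_SET = frozenset(SBS96_CHANNELS)


# --- ID83 ---------------------------------------------------------------------

def _id83_channels() -> list[str]:
    out = []
    # 1bp deletions/insertions in homopolymers
    for base in ("C", "T"):
        out += [f"DEL.{base}.1.{n}" for n in ("1", "2", "3", "4", "5", "6+")]
    for base in ("C", "T"):
        out += [f"INS.{base}.1.{n}" for n in ("0", "1", "2", "3", "4", "5+")]
    # >=2bp indels at repeats, binned by indel size and repeat count
    for size in ("2", "3", "4", "5+"):
        out += [f"DEL.repeats.{size}.{n}" for n in ("1", "2", "3", "4", "5", "6+")]
    for size in ("2", "3", "4", "5+"):
        out += [f"INS.repeats.{size}.{n}" for n in ("0", "1", "2", "3", "4", "5+")]
    # deletions at microhomology: size x homology length
    for size, mhs in (("2", ("1",)), ("3", ("1", "2")), ("4", ("1", "2", "3")),
                      ("5+", ("1", "2", "3", "4", "5+"))):
        out += [f"DEL.MH.{size}.{mh}" for mh in mhs]
    return out


ID83_CHANNELS: tuple[str, ...] = tuple(_id83_channels())
assert len(ID83_CHANNELS) == 83

_DEL_MH_CAPS = {2: 1, 3: 2, 4: 3}  # max homology length representable per size bin


def _size_bin(size: int) -> str:
    return str(size) if size < 5 else "5+"


def id83_channel(is_deletion: bool, size: int, base: str | None,
                 repeat_count: int, mh_len: int) -> str:
    """Classify one indel onto an ID83 channel.

    ``repeat_count`` is the number of copies of the indel sequence in the
    *reference* (a deletion always has >= 1; an insertion may have 0).  Deletions
    of >= 2 bp that are not in a repeat tract (repeat_count == 1) but flanked by
    microhomology go to the DEL.MH channels.
    """
    if size < 1:
        raise ValueError("indel size must be >= 1")
    if size == 1:
        if base is None:
            raise ValueError("1-bp indels need the inserted/deleted base")
        b = base if base in ("C", "T") else COMPLEMENT[base]
        if is_deletion:
            n = min(max(repeat_count, 1), 6)
            return f"DEL.{b}.1.{n if n < 6 else '6+'}"
        n = min(max(repeat_count, 0), 5)
        return f"INS.{b}.1.{n if n < 5 else '5+'}"
    sz = _size_bin(size)
    if is_deletion:
        if repeat_count >= 2:
            n = min(repeat_count, 6)
            return f"DEL.repeats.{sz}.{n if n < 6 else '6+'}"
        if mh_len >= 1:
            if size >= 5:
                return f"DEL.MH.5+.{'5+' if mh_len >= 5 else mh_len}"
            return f"DEL.MH.{sz}.{min(mh_len, _DEL_MH_CAPS[size])}"
        return f"DEL.repeats.{sz}.1"
    n = min(max(repeat_count, 0), 5)
    return f"INS.repeats.{sz}.{n if n < 5 else '5+'}"


ID83_MH_CHANNELS: tuple[str, ...] = tuple(c for c in ID83_CHANNELS if c.startswith("DEL.MH."))
ID83_DEL_CHANNELS: tuple[str, ...] = tuple(c for c in ID83_CHANNELS if c.startswith("DEL."))


# --- SV32 ---------------------------------------------------------------------

SV_SIZE_BINS = ("<10kb", "10-100kb", "100kb-1Mb", "1-10Mb", ">10Mb")
_SV_SIZE_EDGES = (10_000, 100_000, 1_000_000, 10_000_000)


def sv_size_bin(size: int) -> str:
    for edge, label in zip(_SV_SIZE_EDGES, SV_SIZE_BINS):
        if size < edge:
            return label
    return SV_SIZE_BINS[-1]


def _sv32_channels() -> list[str]:
    out = []
    for clust in ("clustered", "non-clustered"):
        for svt in ("DEL", "DUP", "INV"):
            out += [f"{clust}.{svt}.{b}" for b in SV_SIZE_BINS]
        out.append(f"{clust}.TRA")
    return out


SV32_CHANNELS: tuple[str, ...] = tuple(_sv32_channels())
assert len(SV32_CHANNELS) == 32


def sv32_channel(sv_type: str, size: int | None, clustered: bool) -> str:
    clust = "clustered" if clustered else "non-clustered"
    if sv_type == "TRA":
        return f"{clust}.TRA"
    if size is None:
        raise ValueError(f"{sv_type} requires a size")
    return f"{clust}.{sv_type}.{sv_size_bin(size)}"


CHANNELS_BY_CLASS = {
    "SBS96": SBS96_CHANNELS,
    "ID83": ID83_CHANNELS,
    "SV32": SV32_CHANNELS,
}
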