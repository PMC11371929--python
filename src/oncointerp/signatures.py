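"""Mutational catalogs and signature refitting.

Catalogs are integer count vectors over the SBS96, ID83 or SV32 channels.
Exposures are fitted by non-negative least squares against a reference matrix
whose columns live on the probability simplex, with the active signature set
refined greedily whenever the reconstruction cosine similarity falls below 0.90.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .channels import (CHANNELS_BY_CLASS, ID83_DEL_CHANNELS, ID83_MH_CHANNELS,
                       id83_channel, sbs96_channel, sv32_channel)
from .records import SVRecord, ValidationError, VariantRecord
from .refsigs import MSI_SIGNATURES

COSINE_REFINEMENT_TRIGGER = 0.90   # refit is "sufficient" at >= 0.90 (strict <0.90 triggers)
FORWARD_GAIN_MIN = 0.005           # minimum cosine gain to accept a forward addition
PRUNE_EXPOSURE_FRACTION = 0.01     # backward-prune signatures attributing < 1%
PRUNE_COSINE_COST = 0.005          # ... if removal costs < this much cosine


@dataclass
class MutationalCatalog:
    sig_class: str
    counts: np.ndarray

    def __post_init__(self):
        channels = CHANNELS_BY_CLASS.get(self.sig_class)
        if channels is None:
            raise ValidationError(f"unknown signature class {self.sig_class!r}")
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(channels),):
            raise ValidationError(
                f"{self.sig_class} catalog needs {len(channels)} channels, "
                f"got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValidationError("catalog counts must be non-negative")

    @property
    def channels(self) -> tuple[str, ...]:
        return CHANNELS_BY_CLASS[self.sig_class]

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.channels, self.counts.tolist()))


@dataclass
class SignatureReference:
    """Channels x signatures probability matrix (each column sums to 1)."""
    sig_class: str
    names: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        channels = CHANNELS_BY_CLASS.get(self.sig_class)
        if channels is None:
            raise ValidationError(f"unknown signature class {self.sig_class!r}")
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(channels), len(self.names)):
            raise ValidationError(
                f"reference shape {self.matrix.shape} does not match "
                f"{len(channels)} channels x {len(self.names)} signatures")
        sums = self.matrix.sum(axis=0)
        if np.abs(sums - 1.0).max() > 1e-3:
            bad = [n for n, s in zip(self.names, sums) if abs(s - 1.0) > 1e-3]
            raise ValidationError(f"signature columns do not sum to 1: {bad}")
        if np.abs(sums - 1.0).max() > 1e-6:
            self.matrix = self.matrix / sums  # renormalize small drift

    def columns(self, names: list[str]) -> np.ndarray:
        idx = [self.names.index(n) for n in names]
        return self.matrix[:, idx]

    def mixture_distribution(self, weights: dict[str, float]) -> np.ndarray:
        missing = [n for n in weights if n not in self.names]
        if missing:
            raise ValidationError(f"signatures absent from reference: {missing}")
        w = np.array([weights.get(n, 0.0) for n in self.names])
        if (w < 0).any():
            raise ValidationError("mixture weights must be non-negative")
        total = w.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValidationError(f"mixture weights sum to {total}, expected 1")
        return self.matrix @ w


@dataclass
class SignatureExposure:
    sig_class: str
    exposures: dict[str, float]
    cosine: float
    active_set: list[str]
    refinement_trace: list[str] = field(default_factory=list)
    degenerate: bool = False
    best_effort: bool = False

    @property
    def total(self) -> float:
        return float(sum(self.exposures.values()))

    def fraction(self, *signatures: str) -> float:
        """Fraction of attributed mutations assigned to the given signatures."""
        tot = self.total
        if tot == 0:
            return 0.0
        return sum(self.exposures.get(s, 0.0) for s in signatures) / tot

    def fraction_percent(self, *signatures: str, decimals: int = 1) -> float:
        """Signature fraction as a percentage, half-up rounded."""
        from .reporting_utils import round_half_up
        return round_half_up(100.0 * self.fraction(*signatures), decimals)


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 1.0  # degenerate; callers flag this
    return float(np.dot(a, b) / (na * nb))


# --- catalog builders ---------------------------------------------------------

def build_sbs96_catalog(records: list[VariantRecord]) -> MutationalCatalog:
    """Tally SNVs onto the 96 pyrimidine-strand substitution channels."""
    channels = CHANNELS_BY_CLASS["SBS96"]
    index = {c: i for i, c in enumerate(channels)}
    counts = np.zeros(len(channels))
    for rec in records:
        if rec.trinucleotide_context is None:
            raise ValidationError(f"record at {rec.chrom}:{rec.pos} has no context")
        ch = sbs96_channel(rec.ref, rec.alt, rec.trinucleotide_context)
        counts[index[ch]] += 1
    return MutationalCatalog("SBS96", counts)


def build_id83_catalog(records: list[VariantRecord]) -> MutationalCatalog:
    channels = CHANNELS_BY_CLASS["ID83"]
    index = {c: i for i, c in enumerate(channels)}
    counts = np.zeros(len(channels))
    for rec in records:
        feats = rec.indel_features
        if feats is None:
            raise ValidationError(f"record at {rec.chrom}:{rec.pos} has no indel features")
        size = rec.indel_size
        base = None
        if size == 1:
            longer = rec.ref if rec.is_deletion else rec.alt
            base = longer[-1]
        ch = id83_channel(rec.is_deletion, size, base, feats.repeat_count, feats.mh_len)
        counts[index[ch]] += 1
    return MutationalCatalog("ID83", counts)


def flag_clustered_breakpoints(svs: list[SVRecord], window: int = 1_000_000,
                               min_breakpoints: int = 8) -> list[bool]:
    """Flag each SV whose breakpoints fall in a dense region.

    An SV is clustered when either of its breakpoints lies inside some window of
    ``window`` bp containing >= ``min_breakpoints`` breakpoints (from any SV).
    """
    by_chrom: dict[str, list[int]] = {}
    for sv in svs:
        by_chrom.setdefault(sv.chrom_a, []).append(sv.pos_a)
        by_chrom.setdefault(sv.chrom_b, []).append(sv.pos_b)
    sorted_pos = {c: np.array(sorted(p)) for c, p in by_chrom.items()}

    def dense(chrom: str, pos: int) -> bool:
        arr = sorted_pos[chrom]
        # max breakpoint count over windows [x, x+window] containing pos
        lo = np.searchsorted(arr, pos - window, side="left")
        hi = np.searchsorted(arr, pos + window, side="right")
        cand = arr[lo:hi]
        for start in cand:
            if start > pos:
                break
            n = np.searchsorted(arr, start + window, side="right") - \
                np.searchsorted(arr, start, side="left")
            if n >= min_breakpoints:
                return True
        return False

    return [dense(sv.chrom_a, sv.pos_a) or dense(sv.chrom_b, sv.pos_b) for sv in svs]


def build_sv32_catalog(svs: list[SVRecord],
                       clustered: list[bool] | None = None) -> MutationalCatalog:
    """Tally SVs onto the 32 rearrangement channels.

    ``clustered`` flags may be supplied; otherwise they are computed with the
    breakpoint-density rule of :func:`flag_clustered_breakpoints`.
    """
    if clustered is None:
        clustered = flag_clustered_breakpoints(svs)
    channels = CHANNELS_BY_CLASS["SV32"]
    index = {c: i for i, c in enumerate(channels)}
    counts = np.zeros(len(channels))
    for sv, cl in zip(svs, clustered):
        counts[index[sv32_channel(sv.sv_type, sv.size, cl)]] += 1
    return MutationalCatalog("SV32", counts)


# --- fitting ------------------------------------------------------------------

def fit_exposures_nnls(catalog: MutationalCatalog, reference: SignatureReference,
                       active_set: list[str] | None = None) -> SignatureExposure:
    """Fit non-negative exposures to the catalog over the active signature set.

    Exposures are rescaled so attributed counts sum to the catalog total
    (when the raw fit is non-degenerate).
    """
    if reference.sig_class != catalog.sig_class:
        raise ValidationError(
            f"reference class {reference.sig_class} != catalog class {catalog.sig_class}")
    if active_set is None:
        active_set = list(reference.names)
    if not active_set:
        raise ValidationError("active signature set must be non-empty")
    missing = [n for n in active_set if n not in reference.names]
    if missing:
        raise ValidationError(f"signatures absent from reference: {missing}")

    c = catalog.counts
    if c.sum() == 0:
        return SignatureExposure(catalog.sig_class, {n: 0.0 for n in active_set},
                                 cosine=1.0, active_set=list(active_set),
                                 degenerate=True)
    M = reference.columns(active_set)
    x, _ = nnls(M, c)
    recon = M @ x
    cos = cosine_similarity(c, recon)
    if x.sum() > 0:
        x = x * (c.sum() / x.sum())
    return SignatureExposure(catalog.sig_class,
                             dict(zip(active_set, x.tolist())),
                             cosine=cos, active_set=list(active_set))


def refine_signature_set(catalog: MutationalCatalog, reference: SignatureReference,
                         initial_set: list[str]) -> SignatureExposure:
    """Refit with greedy signature-set refinement.

    If the initial fit reconstructs the catalog at cosine >= 0.90 it is returned
    unchanged.  Otherwise candidate signatures from the full reference are added
    one at a time (largest cosine gain first, gains below 0.005 rejected) until
    the 0.90 threshold is reached, then signatures attributing < 1% of mutations
    are pruned when their removal costs < 0.005 cosine.
    """
    fit = fit_exposures_nnls(catalog, reference, initial_set)
    trace: list[str] = []
    if fit.cosine >= COSINE_REFINEMENT_TRIGGER or fit.degenerate:
        return fit

    active = list(initial_set)
    while fit.cosine < COSINE_REFINEMENT_TRIGGER:
        candidates = [n for n in reference.names if n not in active]
        best_name, best_fit = None, None
        for name in candidates:
            trial = fit_exposures_nnls(catalog, reference, active + [name])
            if best_fit is None or trial.cosine > best_fit.cosine:
                best_name, best_fit = name, trial
        if best_fit is None or best_fit.cosine - fit.cosine <= FORWARD_GAIN_MIN:
            break
        active.append(best_name)
        trace.append(f"+{best_name}")
        fit = best_fit

    # backward pruning of negligible contributors
    changed = True
    while changed and len(active) > 1:
        changed = False
        total = fit.total
        for name in list(active):
            if total > 0 and fit.exposures.get(name, 0.0) / total < PRUNE_EXPOSURE_FRACTION:
                trial = fit_exposures_nnls(catalog, reference,
                                           [n for n in active if n != name])
                if fit.cosine - trial.cosine < PRUNE_COSINE_COST:
                    active.remove(name)
                    trace.append(f"-{name}")
                    fit = trial
                    changed = True
                    break

    fit.refinement_trace = trace
    fit.best_effort = fit.cosine < COSINE_REFINEMENT_TRIGGER
    return fit


def msi_signature_proportion(exposure: SignatureExposure) -> float:
    """Fraction of SBS mutations attributed to the seven MSI-associated signatures."""
    if exposure.sig_class != "SBS96":
        raise ValidationError("MSI signature proportion is defined on SBS exposures")
    return exposure.fraction(*MSI_SIGNATURES)


def mh_deletion_proportion(id_catalog: MutationalCatalog) -> float:
    """Microhomology deletions as a fraction of all deletion-class indels (0 if none)."""
    if id_catalog.sig_class != "ID83":
        raise ValidationError("microhomology proportion is defined on ID83 catalogs")
    d = id_catalog.as_dict()
    dels = sum(d[c] for c in ID83_DEL_CHANNELS)
    if dels == 0:
        return 0.0
    return sum(d[c] for c in ID83_MH_CHANNELS) / dels
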