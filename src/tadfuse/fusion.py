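"""Derivative (translocated) chromosome construction and coordinate lifting.

A reciprocal translocation joins the head of one chromosome to the tail of
another, producing a derivative chromosome such as der(13) t(2;13).  The
breakpoint junction may carry a short insertion.  This module builds the
fused sequence, maintains bidirectional coordinate maps between native and
derivative coordinates, duplicates reads unique to the derivative allele to
compensate for copy number, and balances 4C signal across the junction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fragmap import GenomeSequence

__all__ = [
    "BreakpointSpec",
    "DerivativeGenome",
    "build_derivative",
    "native_to_derivative",
    "derivative_to_native",
    "rescale_derivative",
    "balance_sides",
]

INSERTION = "insertion"


@dataclass(frozen=True)
class BreakpointSpec:
    """Junction definition: chromA[0:posA] + insertion + chromB[posB:].

    ``posA`` is exclusive (first base NOT retained from chromA), ``posB``
    inclusive (first base retained from chromB); bases of any junction
    micro-homology are attributed to chromA.
    """

    chromA: str
    posA: int
    chromB: str
    posB: int
    insertion: str = ""

    def __post_init__(self):
        if set(self.insertion) - set("ACGT"):
            raise ValueError("insertion must be over {A,C,G,T}")


@dataclass(frozen=True)
class DerivativeGenome:
    """Segment table mapping derivative coordinates back to their sources.

    ``segments`` is an ordered tuple of (source chrom, source start, source
    end, derivative offset); the insertion segment uses the pseudo-source
    name ``"insertion"``.  Segments exactly tile ``[0, length)``.
    """

    spec: BreakpointSpec
    segments: tuple[tuple[str, int, int, int], ...]
    length: int
    name: str = "der"

    @property
    def junction(self) -> int:
        """Derivative coordinate of the first base after the chromA part."""
        return self.spec.posA


def build_derivative(
    genome: dict[str, str],
    spec: BreakpointSpec,
    name: str = "der",
) -> tuple[DerivativeGenome, GenomeSequence]:
    """Fuse two native chromosomes into the derivative sequence."""
    for chrom in (spec.chromA, spec.chromB):
        if chrom not in genome:
            raise ValueError(f"chromosome {chrom!r} not in genome")
    seqA, seqB = genome[spec.chromA], genome[spec.chromB]
    if not (0 <= spec.posA <= len(seqA)):
        raise ValueError(f"posA {spec.posA} out of range for {spec.chromA}")
    if not (0 <= spec.posB <= len(seqB)):
        raise ValueError(f"posB {spec.posB} out of range for {spec.chromB}")

    ins = spec.insertion
    segments: list[tuple[str, int, int, int]] = []
    offset = 0
    if spec.posA > 0:
        segments.append((spec.chromA, 0, spec.posA, 0))
        offset = spec.posA
    if ins:
        segments.append((INSERTION, 0, len(ins), offset))
        offset += len(ins)
    if spec.posB < len(seqB):
        segments.append((spec.chromB, spec.posB, len(seqB), offset))
        offset += len(seqB) - spec.posB

    seq = seqA[: spec.posA] + ins + seqB[spec.posB:]
    dg = DerivativeGenome(spec=spec, segments=tuple(segments),
                          length=offset, name=name)
    return dg, GenomeSequence(name, seq)


def native_to_derivative(dg: DerivativeGenome, chrom: str, pos: int) -> int | None:
    """Map a native (chrom, pos) to its derivative coordinate, if retained."""
    for src, s0, s1, off in dg.segments:
        if src == chrom and s0 <= pos < s1:
            return off + (pos - s0)
    return None


def derivative_to_native(dg: DerivativeGenome, pos: int) -> tuple[str, int]:
    """Map a derivative coordinate to (source chrom, source position).

    Positions inside the junction insertion map to ("insertion", offset).
    """
    if not (0 <= pos < dg.length):
        raise ValueError(f"derivative position {pos} out of range [0, {dg.length})")
    for src, s0, s1, off in dg.segments:
        if off <= pos < off + (s1 - s0):
            return src, s0 + (pos - off)
    raise AssertionError("segments do not tile the derivative")  # pragma: no cover


def rescale_derivative(profile, dg: DerivativeGenome):
    """Duplicate counts unique to the derivative allele.

    In a cell carrying one derivative and intact homologs, 4C reads on the
    viewpoint's own native chromosome arise from two alleles while reads
    beyond the breakpoint are unique to the derivative; the far side is
    therefore doubled to restore equal theoretical copy number.  Raw counts
    are rescaled (before smoothing).  Refuses a second application.
    """
    if profile.derivative_rescaled:
        raise ValueError("profile already derivative-rescaled")
    if profile.raw is None:
        raise ValueError("raw layer not filled")
    vp_pos = profile.viewpoint.position
    junction = dg.junction
    ins_len = len(dg.spec.insertion)
    vp_chrom, _ = derivative_to_native(dg, vp_pos)
    if vp_chrom == INSERTION:
        raise ValueError("viewpoint inside the junction insertion; side undefined")
    vp_on_A = vp_chrom == dg.spec.chromA
    # Guard: viewpoint on the fragment spanning the junction has no defined side.
    vb = profile.frag_bounds
    vp_rows = (vb[:, 0] <= vp_pos) & (vp_pos < vb[:, 1])
    if vp_rows.any():
        s, e = vb[vp_rows][0]
        if s < junction < e or s < junction + ins_len < e:
            raise ValueError("viewpoint on the junction fragment; side undefined")

    out = profile.copy()
    far = (profile.ends >= junction) if vp_on_A else (profile.ends < junction + ins_len)
    out.raw = profile.raw.copy()
    out.raw[far] *= 2.0
    out.derivative_rescaled = True
    return out


def balance_sides(profile, breakpoint_pos: int, flank: int):
    """Equalise smoothed 4C signal across the breakpoint.

    Computes the mean smoothed signal in the two windows of ``flank`` bp
    adjacent to the breakpoint and rescales each whole side toward the
    geometric mean of the two flank means, so the operation is symmetric and
    independent of which side is called "left".  The applied scalars are
    recorded on the profile.
    """
    if profile.smoothed is None:
        raise ValueError("smoothed layer not filled")
    if flank <= 0:
        raise ValueError("flank must be positive")
    e = profile.ends
    left_sel = (e >= breakpoint_pos - flank) & (e < breakpoint_pos)
    right_sel = (e >= breakpoint_pos) & (e < breakpoint_pos + flank)
    mL = float(profile.smoothed[left_sel].mean()) if left_sel.any() else 0.0
    mR = float(profile.smoothed[right_sel].mean()) if right_sel.any() else 0.0
    if mL <= 0 or mR <= 0:
        raise ValueError("zero mean signal in a breakpoint flank; cannot balance")
    g = float(np.sqrt(mL * mR))
    sL, sR = g / mL, g / mR
    out = profile.copy()
    left_all = e < breakpoint_pos
    out.smoothed = profile.smoothed.copy()
    out.smoothed[left_all] *= sL
    out.smoothed[~left_all] *= sR
    out.side_scalars = (sL, sR)
    return out
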