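"""In-silico restriction digestion and the 4C fragment-end coordinate system.

4C-seq resolves contacts at the level of primary-enzyme restriction
fragments.  This module digests genome sequences with a primary and a
secondary enzyme, flags fragments that are unusable in 4C (``blind``
fragments lacking an internal secondary site, and fragments shorter than a
minimum length), and exposes the filtered fragment-end coordinates that all
downstream profile operations are expressed in.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GenomeSequence",
    "RestrictionFragment",
    "FragmentMap",
    "digest_genome",
    "valid_fragments",
]

_VALID_SITE = set("ACGT")


@dataclass(frozen=True)
class GenomeSequence:
    """A named chromosome sequence over the alphabet {A, C, G, T, N}."""

    name: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class RestrictionFragment:
    """One primary-enzyme fragment, 0-based half-open on its chromosome.

    ``blind`` marks fragments with no secondary-enzyme site strictly inside;
    ``short`` marks fragments below the minimum length.  Either flag makes
    the fragment unobservable in 4C.
    """

    chrom: str
    start: int
    end: int
    index: int
    blind: bool
    short: bool

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def ends(self) -> tuple[int, int]:
        """The two fragment-end coordinates (first and last base).

        Using ``end - 1`` for the downstream end keeps end coordinates
        unique along a chromosome even when retained fragments are adjacent.
        """
        return (self.start, self.end - 1)


@dataclass
class FragmentMap:
    """Ordered restriction fragments per chromosome.

    ``fragments`` maps chromosome name to the ordered fragment list; the
    fragments of each chromosome tile ``[0, length)`` without gaps.
    """

    fragments: dict[str, list[RestrictionFragment]]
    primary_site: str
    secondary_site: str
    min_len: int = 40
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def chromosomes(self) -> list[str]:
        return list(self.fragments)

    def all_fragments(self) -> list[RestrictionFragment]:
        return [f for frs in self.fragments.values() for f in frs]

    def fragment_at(self, chrom: str, pos: int) -> RestrictionFragment:
        """Fragment containing base ``pos`` (binary search on starts)."""
        frs = self.fragments[chrom]
        starts = [f.start for f in frs]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i < 0 or pos >= frs[i].end:
            raise ValueError(f"position {pos} outside {chrom}")
        return frs[i]

    def summary(self) -> dict[str, int]:
        frs = self.all_fragments()
        return {
            "n_fragments": len(frs),
            "n_blind": sum(f.blind for f in frs),
            "n_short": sum(f.short for f in frs),
        }


def _check_site(site: str, what: str) -> None:
    if not site:
        raise ValueError(f"{what} recognition sequence is empty")
    bad = set(site) - _VALID_SITE
    if bad:
        raise ValueError(f"{what} site contains invalid characters: {sorted(bad)}")
    if site != _revcomp(site):
        raise ValueError(f"{what} site {site!r} is not palindromic; only "
                         "palindromic sites are supported (forward-strand scan)")


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _find_sites(seq: str, site: str) -> list[int]:
    """All start positions of ``site`` in ``seq``, overlapping, leftmost scan."""
    hits = []
    i = seq.find(site)
    while i != -1:
        hits.append(i)
        i = seq.find(site, i + 1)
    return hits


def digest_genome(
    genome: dict[str, str] | list[GenomeSequence],
    primary_site: str,
    secondary_site: str,
    min_len: int = 40,
) -> FragmentMap:
    """Digest sequences with the primary enzyme and flag blind/short fragments.

    Fragment boundaries sit at the start coordinate of every primary-site
    occurrence plus the chromosome ends.  A fragment is ``blind`` iff no
    secondary-site occurrence starts strictly inside the fragment (start
    position in ``[start + 1, end - 1)``), and ``short`` iff its length is
    below ``min_len`` (strict).  N bases never match a site; both sites must
    be palindromic (the scan is forward-strand only).
    """
    if isinstance(genome, dict):
        records = [GenomeSequence(n, s) for n, s in genome.items()]
    else:
        records = list(genome)
    if not records:
        raise ValueError("empty genome: no sequences to digest")
    _check_site(primary_site, "primary")
    _check_site(secondary_site, "secondary")

    fragments: dict[str, list[RestrictionFragment]] = {}
    lengths: dict[str, int] = {}
    for rec in records:
        if rec.name in fragments:
            raise ValueError(f"duplicate chromosome name {rec.name!r}")
        seq = rec.seq.upper()
        cuts = _find_sites(seq, primary_site)
        bounds = [0] + [c for c in cuts if c > 0] + [len(seq)]
        bounds = sorted(set(bounds))
        sec = np.asarray(_find_sites(seq, secondary_site), dtype=int)
        frs = []
        for idx, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
            if sec.size:
                lo = int(np.searchsorted(sec, a + 1, side="left"))
                hi = int(np.searchsorted(sec, b - 1, side="left"))
                blind = lo >= hi
            else:
                blind = True
            frs.append(RestrictionFragment(
                chrom=rec.name, start=a, end=b, index=idx,
                blind=blind, short=(b - a) < min_len,
            ))
        fragments[rec.name] = frs
        lengths[rec.name] = len(seq)
    return FragmentMap(fragments=fragments, primary_site=primary_site,
                       secondary_site=secondary_site, min_len=min_len,
                       chrom_lengths=lengths)


def valid_fragments(fmap: FragmentMap) -> FragmentMap:
    """Filtered view retaining non-blind fragments of length >= ``min_len``.

    Reads falling in blind or short fragments are unusable in 4C; this is
    the standard filter applied before converting reads to fragment-end
    units.  Original ``index`` values are preserved for traceability, so the
    operation is idempotent.
    """
    kept = {
        chrom: [f for f in frs if not f.blind and not f.short]
        for chrom, frs in fmap.fragments.items()
    }
    return replace(fmap, fragments=kept)
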