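"""Nuclease off-target search for 21-nt spacers with mismatches and bulges.

Reimplements a Cas-OFFinder-style scan: both strands of the genome are
searched for protospacer-like sites adjacent (3') to a PAM-matching motif,
allowing a bounded number of substitutions plus at most one contiguous
bulge — extra bases on the genomic side (DNA bulge) or on the guide side
(RNA bulge). PAM bases are outside the mismatch budget. The default PAM is
the canonical SaCas9 NNGRRT; it must be overridden for other nucleases.

``search_bruteforce`` is an independent exhaustive enumeration of every
position, strand, site length and bulge placement, kept deliberately
simple; it exists to validate ``search`` and is slow on large genomes.
"""
from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from .simulate import IUPAC, revcomp


@dataclass(frozen=True)
class SpacerQuery:
    """A spacer and its search bounds."""

    spacer: str
    pam_pattern: str = "NNGRRT"
    max_mismatches: int = 3
    max_dna_bulge: int = 2
    max_rna_bulge: int = 1

    def __post_init__(self):
        if len(self.spacer) != 21:
            raise ValueError(f"spacer must be 21 nt, got {len(self.spacer)}")
        if set(self.spacer.upper()) - set("ACGT"):
            raise ValueError("spacer must contain only A/C/G/T")
        if min(self.max_mismatches, self.max_dna_bulge, self.max_rna_bulge) < 0:
            raise ValueError("bounds must be non-negative")
        if set(self.pam_pattern.upper()) - set(IUPAC):
            raise ValueError("PAM pattern must be IUPAC nucleotide codes")
        object.__setattr__(self, "spacer", self.spacer.upper())
        object.__setattr__(self, "pam_pattern", self.pam_pattern.upper())


@dataclass(frozen=True)
class OffTargetHit:
    """One putative off-target site (protospacer coordinates, 0-based
    half-open on the forward strand; PAM is 3' of the protospacer on the
    hit's strand and excluded from the coordinates)."""

    chromosome: str
    start: int
    stop: int
    strand: str
    mismatches: int
    bulge_type: str
    bulge_size: int
    aligned_spacer: str
    aligned_site: str


def align_site(
    spacer: str,
    site: str,
    max_mismatches: int = 3,
    max_dna_bulge: int = 2,
    max_rna_bulge: int = 1,
) -> tuple[int, str, int, str, str] | None:
    """Best gapped alignment of a spacer to a genomic site.

    The length difference fixes the single contiguous bulge: a longer site
    carries a DNA bulge (gap in the spacer), a shorter one an RNA bulge
    (gap in the site); equal lengths align ungapped. Among interior gap
    placements the one with the fewest substitutions wins (leftmost on
    ties). Genomic N never matches. Returns (mismatches, bulge_type,
    bulge_size, aligned_spacer, aligned_site) or None if no alignment is
    within bounds.
    """
    spacer, site = spacer.upper(), site.upper()
    diff = len(site) - len(spacer)
    if diff == 0:
        mm = sum(a != b or b == "N" for a, b in zip(spacer, site))
        if mm > max_mismatches:
            return None
        return mm, "none", 0, spacer, site
    if diff > 0:
        if diff > max_dna_bulge:
            return None
        size, bulge = diff, "dna"
        best = None
        for k in range(1, len(spacer)):
            mm = (sum(a != b or b == "N" for a, b in zip(spacer[:k], site[:k]))
                  + sum(a != b or b == "N" for a, b in zip(spacer[k:], site[k + size:])))
            if best is None or mm < best[0]:
                best = (mm, k)
        mm, k = best
        if mm > max_mismatches:
            return None
        return mm, bulge, size, spacer[:k] + "-" * size + spacer[k:], site
    size, bulge = -diff, "rna"
    if size > max_rna_bulge:
        return None
    best = None
    for k in range(1, len(site)):
        mm = (sum(a != b or b == "N" for a, b in zip(spacer[:k], site[:k]))
              + sum(a != b or b == "N" for a, b in zip(spacer[k + size:], site[k:])))
        if best is None or mm < best[0]:
            best = (mm, k)
    mm, k = best
    if mm > max_mismatches:
        return None
    return mm, bulge, size, spacer, site[:k] + "-" * size + site[k:]


def _pam_regex(pattern: str) -> re.Pattern:
    # genomic N never matches, so classes only contain concrete bases
    parts = [f"[{IUPAC[c]}]" if len(IUPAC[c]) > 1 else IUPAC[c] for c in pattern]
    return re.compile(r"(?=(" + "".join(parts) + r"))")


def search(query: SpacerQuery, genome: dict[str, str]) -> list[OffTargetHit]:
    """All off-target sites of a spacer in a genome, both strands.

    One hit is reported per (chromosome, strand, PAM position): among the
    alternative site lengths anchored at one PAM the alignment minimizing
    (bulge_size, mismatches) lexicographically wins. Hits are sorted by
    (chromosome, start, strand).
    """
    pam_re = _pam_regex(query.pam_pattern)
    lengths = list(range(len(query.spacer) - query.max_rna_bulge,
                         len(query.spacer) + query.max_dna_bulge + 1))
    hits: list[OffTargetHit] = []
    for chrom in sorted(genome):
        seq = genome[chrom].upper()
        n = len(seq)
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            for m in pam_re.finditer(s):
                p = m.start()
                best = None
                for length in lengths:
                    if p - length < 0:
                        continue
                    aln = align_site(query.spacer, s[p - length:p],
                                     query.max_mismatches, query.max_dna_bulge,
                                     query.max_rna_bulge)
                    if aln is None:
                        continue
                    mm, btype, bsize, a_sp, a_si = aln
                    key = (bsize, mm, length)
                    if best is None or key < best[0]:
                        best = (key, length, aln)
                if best is None:
                    continue
                _, length, (mm, btype, bsize, a_sp, a_si) = best
                if strand == "+":
                    start, stop = p - length, p
                else:
                    start, stop = n - p, n - p + length
                hits.append(OffTargetHit(chrom, start, stop, strand, mm, btype,
                                         bsize, a_sp, a_si))
    hits.sort(key=lambda h: (h.chromosome, h.start, h.strand))
    return hits


def search_bruteforce(query: SpacerQuery, genome: dict[str, str]) -> list[OffTargetHit]:
    """Exhaustive off-target enumeration, used as a validation oracle.

    Checks every position and strand for a PAM by direct IUPAC comparison,
    then enumerates every site length and every explicit gap placement,
    recounting substitutions from the aligned strings. Same locus rule and
    sort order as :func:`search`.
    """
    spacer = query.spacer
    hits: list[OffTargetHit] = []
    for chrom in sorted(genome):
        seq = genome[chrom].upper()
        n = len(seq)
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            for p in range(len(s) - len(query.pam_pattern) + 1):
                pam = s[p:p + len(query.pam_pattern)]
                if any(base not in IUPAC[code]
                       for base, code in zip(pam, query.pam_pattern)):
                    continue
                candidates = []
                # ungapped
                if p - len(spacer) >= 0:
                    site = s[p - len(spacer):p]
                    mm = sum(a != b or b == "N" for a, b in zip(spacer, site))
                    if mm <= query.max_mismatches:
                        candidates.append((0, mm, len(site), "none", spacer, site))
                # DNA bulge: site longer by d
                for d in range(1, query.max_dna_bulge + 1):
                    length = len(spacer) + d
                    if p - length < 0:
                        continue
                    site = s[p - length:p]
                    for k in range(1, len(spacer)):
                        gapped = spacer[:k] + "-" * d + spacer[k:]
                        mm = sum(a != "-" and (a != b or b == "N")
                                 for a, b in zip(gapped, site))
                        if mm <= query.max_mismatches:
                            candidates.append((d, mm, length, "dna", gapped, site))
                # RNA bulge: site shorter by d
                for d in range(1, query.max_rna_bulge + 1):
                    length = len(spacer) - d
                    if p - length < 0:
                        continue
                    site = s[p - length:p]
                    for k in range(1, len(site)):
                        gapped_site = site[:k] + "-" * d + site[k:]
                        mm = sum(b != "-" and (a != b or b == "N")
                                 for a, b in zip(spacer, gapped_site))
                        if mm <= query.max_mismatches:
                            candidates.append((d, mm, length, "rna", spacer, gapped_site))
                if not candidates:
                    continue
                # per bulge size+length keep the best placement, then the locus rule
                best = min(candidates, key=lambda c: (c[0], c[1], c[2]))
                bsize, mm, length, btype, a_sp, a_si = best
                if strand == "+":
                    start, stop = p - length, p
                else:
                    start, stop = n - p, n - p + length
                hits.append(OffTargetHit(chrom, start, stop, strand, mm, btype,
                                         bsize, a_sp, a_si))
    hits.sort(key=lambda h: (h.chromosome, h.start, h.strand))
    return hits


def hits_to_frame(hits: list[OffTargetHit]) -> pd.DataFrame:
    cols = ["chromosome", "start", "stop", "strand", "mismatches", "bulge_type",
            "bulge_size", "aligned_spacer", "aligned_site"]
    return pd.DataFrame([vars(h) for h in hits], columns=cols)
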