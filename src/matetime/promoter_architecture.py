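"""Pheromone-response-element (PRE) scanning and nucleosome-overlap annotation.

Ste12, the master mating transcription factor, binds PREs with the consensus
nTGAAACn (canonical 8-mer ATGAAACA); the six core nucleotides TGAAAC matter
most for binding, and degenerate ("non-consensus") sites with mutations in the
core retain reduced affinity.  Promoter sequences are given 5'->3' toward the
ATG, typically the -1000..-1 region, so the 3' end of the sequence abuts the
start codon.  Whether a site sits under a mapped nucleosome decides whether it
is accessible before stimulation; early promoters carry at least two consensus
sites in a nucleosome-depleted region, late ones do not.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from itertools import combinations

from Bio import SeqIO
from Bio.Seq import Seq

CORE = "TGAAAC"
CORE_RC = str(Seq(CORE).reverse_complement())  # GTTTCA
_VALID = set("ACGTN")


class SequenceError(ValueError):
    """Sequence contains characters outside {A, C, G, T, N}."""


@dataclass(frozen=True)
class PREHit:
    """One PRE match on a promoter sequence.

    Coordinates are 0-based half-open on the supplied (plus) strand; minus-
    strand matches are reported in plus-strand coordinates.  ``start``/``end``
    delimit the 8-mer context nTGAAACn, truncated at the sequence edges only
    when the 6-bp core itself is fully inside.
    """

    promoter: str
    start: int
    end: int
    strand: str  # "+" or "-"
    matched: str  # sequence of [start, end) on the plus strand
    core_mismatches: int
    klass: str  # "consensus" (0 core mismatches) or "non_consensus"
    distance_to_atg: int  # bp from site end to the sequence 3' end
    nucleosome_overlap: bool | None = None


def _core_mismatches(window: str, core: str) -> int:
    """Mismatch count of a 6-mer against the core; N never matches."""
    return sum(1 for a, b in zip(window, core) if a != b)


def scan_pre(
    sequence: str, promoter: str = "", max_mismatch: int = 1
) -> list[PREHit]:
    """Scan both strands of a promoter for consensus and degenerate PREs.

    Every placement of the 6-bp core with at most ``max_mismatch`` mismatches
    is reported (overlapping hits included), sorted by start then strand.
    The flanking "n" positions are unconstrained and only widen the reported
    interval to the 8-mer context.
    """
    seq = sequence.upper()
    for i, ch in enumerate(seq):
        if ch not in _VALID:
            raise SequenceError(f"invalid character {ch!r} at offset {i}")
    L = len(seq)
    if L < 8:
        raise ValueError("sequence shorter than 8 bp")
    hits: list[PREHit] = []
    for c in range(L - 6 + 1):
        window = seq[c : c + 6]
        for strand, core in (("+", CORE), ("-", CORE_RC)):
            mm = _core_mismatches(window, core)
            if mm <= max_mismatch:
                start = max(0, c - 1)
                end = min(L, c + 7)
                hits.append(
                    PREHit(
                        promoter=promoter,
                        start=start,
                        end=end,
                        strand=strand,
                        matched=seq[start:end],
                        core_mismatches=mm,
                        klass="consensus" if mm == 0 else "non_consensus",
                        distance_to_atg=L - end,
                    )
                )
    hits.sort(key=lambda h: (h.start, h.strand, h.core_mismatches))
    return hits


def annotate_nucleosomes(
    hits: list[PREHit], intervals: list[tuple[int, int]]
) -> list[PREHit]:
    """Set ``nucleosome_overlap`` on each hit by >= 1 bp interval intersection.

    Intervals are 0-based half-open on the same coordinate frame as the
    promoter sequence; hits with ``nucleosome_overlap=False`` sit in
    nucleosome-depleted (accessible) regions.
    """
    for s, e in intervals:
        if not (isinstance(s, (int,)) and isinstance(e, (int,)) and s < e):
            raise ValueError(f"malformed interval ({s}, {e})")
    out = []
    for h in hits:
        overlap = any(h.start < e and s < h.end for s, e in intervals)
        out.append(replace(h, nucleosome_overlap=overlap))
    return out


def accessible_dimer_pairs(hits: list[PREHit]) -> list[tuple[PREHit, PREHit, int]]:
    """All unordered pairs of accessible consensus sites with their spacing.

    Only consensus hits outside nucleosomes qualify; spacing is center-to-
    center in bp.  An empty list is the signature of late-promoter
    architecture (at most one strong accessible Ste12 site); two or more
    accessible consensus sites mark the early architecture.
    """
    if any(h.nucleosome_overlap is None for h in hits):
        raise ValueError("hits must be nucleosome-annotated first")
    free = [h for h in hits if h.klass == "consensus" and not h.nucleosome_overlap]
    pairs = []
    for a, b in combinations(free, 2):
        spacing = abs((a.start + a.end) / 2.0 - (b.start + b.end) / 2.0)
        pairs.append((a, b, int(round(spacing))))
    return pairs


# ---------------------------------------------------------------------------
# file formats

def read_promoters_fasta(path) -> dict[str, str]:
    """Read promoter sequences (5'->3' toward the ATG) from FASTA."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_nucleosome_bed(path) -> dict[str, list[tuple[int, int]]]:
    """Read nucleosome intervals from a BED file (0-based half-open).

    The first column must match the promoter id used in the FASTA.
    """
    tracks: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line: {line!r}")
            name, s, e = parts[0], int(parts[1]), int(parts[2])
            if s >= e:
                raise ValueError(f"malformed interval ({s}, {e}) in BED")
            tracks.setdefault(name, []).append((s, e))
    return tracks


def write_hits_bed(hits: list[PREHit], path) -> None:
    """Emit hits as BED6: name = consensus class, score = core mismatches."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.promoter}\t{h.start}\t{h.end}\t{h.klass}\t"
                f"{h.core_mismatches}\t{h.strand}\n"
            )


def write_hits_csv(hits: list[PREHit], path) -> None:
    fieldnames = [
        "promoter", "start", "end", "strand", "matched", "core_mismatches",
        "klass", "distance_to_atg", "nucleosome_overlap",
    ]
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=fieldnames)
        w.writeheader()
        for h in hits:
            w.writerow({k: getattr(h, k) for k in fieldnames})
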