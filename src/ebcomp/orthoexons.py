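"""Orthologous-exon reference construction from alignment hit records.

Human protein-coding exons are aligned to the chimpanzee genome; exons are
retained when they pass, in order:

1. sequence identity >= 80% (matches / query exon length);
2. multi-mapping resolution — among loci passing the identity filter, keep
   the locus sharing the most neighboring exons of the same gene within
   100 kb (ties: higher identity, then lexicographically smallest locus);
3. indel content <= 20% of the exon length;
4. reciprocal validation — the chimpanzee exon must map back to the original
   human locus, and map to its own chimpanzee locus, with same-chromosome
   interval overlap (>= 1 base) in both directions.

The retained set is emitted as one GTF per species with shared identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import io as _io

IDENTITY_MIN = 0.80
INDEL_MAX = 0.20
NEIGHBOR_WINDOW = 100_000

# first-failing reason codes, evaluated in filter order
REASON_IDENTITY = "low_identity"
REASON_INDEL = "indel"
REASON_RECIP_HUMAN = "reciprocal-human"
REASON_RECIP_CHIMP = "reciprocal-chimp"
REASON_NO_RECIP = "no-reciprocal-hit"


class InvalidRecordError(ValueError):
    pass


@dataclass(frozen=True)
class AlignmentHit:
    """One alignment of a query exon onto a target genome (PSL semantics)."""

    query_exon_id: str
    query_gene_id: str
    query_length: int
    matches: int
    mismatches: int
    query_gap_bases: int
    target_gap_bases: int
    target_chrom: str
    target_start: int
    target_end: int
    strand: str
    source_locus: tuple  # (chrom, start, end) of the query in its own genome

    def __post_init__(self):
        if self.target_end <= self.target_start:
            raise InvalidRecordError(
                f"{self.query_exon_id}: target_end must exceed target_start")
        if self.matches + self.mismatches > self.query_length:
            raise InvalidRecordError(
                f"{self.query_exon_id}: matches + mismatches exceed query length")
        if self.query_gap_bases < 0 or self.target_gap_bases < 0:
            raise InvalidRecordError(f"{self.query_exon_id}: negative gap bases")


@dataclass
class OrthologySet:
    """Outcome of the filter cascade: retained loci and dropped reasons."""

    retained: dict = field(default_factory=dict)  # exon_id -> AlignmentHit
    dropped: dict = field(default_factory=dict)   # exon_id -> reason code

    def check(self):
        overlap = set(self.retained) & set(self.dropped)
        if overlap:
            raise ValueError(f"exons both retained and dropped: {sorted(overlap)}")
        return self


def sequence_identity(hit: AlignmentHit) -> float:
    """matches / query exon length, in [0, 1].

    The denominator is the full query length (not the aligned span), so
    unaligned exon ends count against identity.
    """
    if hit.query_length <= 0:
        raise InvalidRecordError(f"{hit.query_exon_id}: query_length must be > 0")
    return hit.matches / hit.query_length


def indel_fraction(hit: AlignmentHit) -> float:
    """(query gap bases + target gap bases) / query exon length."""
    if hit.query_length <= 0:
        raise InvalidRecordError(f"{hit.query_exon_id}: query_length must be > 0")
    return (hit.query_gap_bases + hit.target_gap_bases) / hit.query_length


def _locus_key(hit: AlignmentHit):
    return (hit.target_chrom, hit.target_start, hit.target_end)


def _neighbor_support(hit: AlignmentHit, gene_exon_loci: dict) -> int:
    """Count same-gene exons with a candidate locus within 100 kb of ``hit``.

    A neighboring exon supports the locus only if every one of its in-window
    candidate hits lies on the strand of ``hit`` (mixed-strand support counts
    as non-support). Distance is measured between exon start coordinates.
    """
    n = 0
    for exon_id, cand_hits in gene_exon_loci.items():
        if exon_id == hit.query_exon_id:
            continue
        in_window = [h for h in cand_hits
                     if h.target_chrom == hit.target_chrom
                     and abs(h.target_start - hit.target_start) <= NEIGHBOR_WINDOW]
        if in_window and all(h.strand == hit.strand for h in in_window):
            n += 1
    return n


def resolve_multimapping(hits_for_one_exon, gene_exon_loci) -> AlignmentHit | None:
    """Pick one locus for a multi-mapping exon by same-gene neighbor support.

    ``gene_exon_loci`` maps exon id -> candidate hits for every exon of the
    gene (identity-passing hits). Ties on the neighbor count break by higher
    identity, then lexicographically smallest (chrom, start, end).
    """
    hits = list(hits_for_one_exon)
    if not hits:
        return None
    if len(hits) == 1:
        return hits[0]
    scored = [
        (-_neighbor_support(h, gene_exon_loci), -sequence_identity(h), _locus_key(h))
        for h in hits
    ]
    best = min(range(len(hits)), key=lambda i: scored[i])
    return hits[best]


def _intervals_overlap(chrom_a, start_a, end_a, chrom_b, start_b, end_b) -> bool:
    return chrom_a == chrom_b and start_a < end_b and start_b < end_a


def _best_by_exon(hits):
    best = {}
    for h in hits:
        cur = best.get(h.query_exon_id)
        if cur is None or sequence_identity(h) > sequence_identity(cur):
            best[h.query_exon_id] = h
    return best


def reciprocal_validate(forward: OrthologySet, back_to_human, chimp_self) -> OrthologySet:
    """Keep exons whose best back-maps overlap the original loci both ways.

    ``back_to_human``: hits of the chimpanzee exon on the human genome; the
    best hit must overlap the exon's human source locus. ``chimp_self``:
    hits of the chimpanzee exon on the chimpanzee genome; the best hit must
    overlap the retained chimpanzee locus. Overlap = same chromosome and
    >= 1 shared base.
    """
    back_h = _best_by_exon(back_to_human)
    back_c = _best_by_exon(chimp_self)
    out = OrthologySet(dropped=dict(forward.dropped))
    for exon_id, hit in forward.retained.items():
        bh = back_h.get(exon_id)
        bc = back_c.get(exon_id)
        if bh is None or bc is None:
            out.dropped[exon_id] = REASON_NO_RECIP
            continue
        src_chrom, src_start, src_end = hit.source_locus
        if not _intervals_overlap(bh.target_chrom, bh.target_start, bh.target_end,
                                  src_chrom, src_start, src_end):
            out.dropped[exon_id] = REASON_RECIP_HUMAN
            continue
        if not _intervals_overlap(bc.target_chrom, bc.target_start, bc.target_end,
                                  hit.target_chrom, hit.target_start, hit.target_end):
            out.dropped[exon_id] = REASON_RECIP_CHIMP
            continue
        out.retained[exon_id] = hit
    return out.check()


def apply_forward_filters(forward_hits) -> OrthologySet:
    """Identity filter, per-gene multimap resolution, then the indel filter."""
    by_exon: dict[str, list[AlignmentHit]] = {}
    gene_of: dict[str, str] = {}
    for h in forward_hits:
        by_exon.setdefault(h.query_exon_id, []).append(h)
        gene_of[h.query_exon_id] = h.query_gene_id
    passing: dict[str, list[AlignmentHit]] = {}
    out = OrthologySet()
    for exon_id, hits in by_exon.items():
        ok = [h for h in hits if sequence_identity(h) >= IDENTITY_MIN]
        if not ok:
            out.dropped[exon_id] = REASON_IDENTITY
        else:
            passing[exon_id] = ok
    by_gene: dict[str, dict[str, list[AlignmentHit]]] = {}
    for exon_id, hits in passing.items():
        by_gene.setdefault(gene_of[exon_id], {})[exon_id] = hits
    for exon_id, hits in sorted(passing.items()):
        chosen = resolve_multimapping(hits, by_gene[gene_of[exon_id]])
        if indel_fraction(chosen) > INDEL_MAX:
            out.dropped[exon_id] = REASON_INDEL
        else:
            out.retained[exon_id] = chosen
    return out.check()


def run_filters(forward_hits, back_to_human, chimp_self) -> OrthologySet:
    """The full cascade: identity -> multimap -> indel -> reciprocity."""
    return reciprocal_validate(apply_forward_filters(forward_hits),
                               back_to_human, chimp_self)


def build_reference(ortho: OrthologySet, out_dir, gene_of=None):
    """Emit one GTF per species from the retained set, plus a dropped TSV.

    Returns the paths (human_gtf, chimp_gtf, dropped_tsv). Both GTFs carry
    identical gene and exon identifiers; exon counts are equal by
    construction.
    """
    import pandas as pd
    from pathlib import Path

    if not ortho.retained:
        raise ValueError("no retained exons; cannot build a reference")
    seen = set()
    human_records, chimp_records = [], []
    for exon_id, hit in sorted(ortho.retained.items()):
        if exon_id in seen:
            raise ValueError(f"duplicate exon id {exon_id}")
        seen.add(exon_id)
        gene = hit.query_gene_id if gene_of is None else gene_of[exon_id]
        src_chrom, src_start, src_end = hit.source_locus
        human_records.append(dict(chrom=src_chrom, start=src_start, end=src_end,
                                  strand="+", gene_id=gene, exon_id=exon_id))
        chimp_records.append(dict(chrom=hit.target_chrom, start=hit.target_start,
                                  end=hit.target_end, strand=hit.strand,
                                  gene_id=gene, exon_id=exon_id))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    human_gtf = out / "human.gtf"
    chimp_gtf = out / "chimp.gtf"
    dropped_tsv = out / "dropped_exons.tsv"
    _io.write_gtf(human_gtf, human_records)
    _io.write_gtf(chimp_gtf, chimp_records)
    _io.write_tsv(dropped_tsv, pd.DataFrame(
        sorted(ortho.dropped.items()), columns=["exon_id", "reason"]))
    return human_gtf, chimp_gtf, dropped_tsv
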