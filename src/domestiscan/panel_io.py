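"""Aligned accession-panel I/O and the upstream coordinate frame.

A *panel* is a gapped multiple alignment of one candidate region across a
set of accessions, joined to per-accession metadata (population group and a
binary phenotype).  Because the region of interest lies upstream of a
translation start site, every reported position is expressed in "bp
upstream of the ATG": alignment column 0 (the distal edge) maps to
``anchor_upstream_bp`` and positions decrease left to right toward the gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentError, MetadataError

logger = logging.getLogger(__name__)

#: Alphabet accepted in panel alignments. Anything else is masked to N.
VALID_SYMBOLS = frozenset("ACGT-N")

GROUPS = ("wild", "cultivated")
PHENOTYPES = ("spread", "compact")


@dataclass(frozen=True)
class AccessionMeta:
    """Metadata for one accession: population group and panicle phenotype."""

    id: str
    group: str
    phenotype: str
    origin: str | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise MetadataError(
                f"accession {self.id!r}: group must be one of {GROUPS}, got {self.group!r}"
            )
        if self.phenotype not in PHENOTYPES:
            raise MetadataError(
                f"accession {self.id!r}: phenotype must be one of {PHENOTYPES}, "
                f"got {self.phenotype!r}"
            )


@dataclass
class Panel:
    """An aligned accession panel over a single upstream regulatory region.

    Parameters
    ----------
    sequences
        Mapping accession id -> aligned sequence over {A, C, G, T, -, N}.
        All sequences must have equal length.
    meta
        One :class:`AccessionMeta` per sequence, ids matching exactly.
    anchor_upstream_bp
        Distance of alignment column 0 from the translation start, in bp
        upstream.  Must be >= the alignment length so the whole region lies
        upstream of the ATG.
    """

    sequences: dict[str, str]
    meta: list[AccessionMeta] = field(repr=False)
    anchor_upstream_bp: int

    def __post_init__(self) -> None:
        if not self.sequences:
            raise AlignmentError("panel has no sequences")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise AlignmentError(f"aligned sequences differ in length: {sorted(lengths)}")
        (self._length,) = lengths
        if self._length < 1:
            raise AlignmentError("alignment length must be >= 1")
        ids = list(self.sequences)
        meta_ids = [m.id for m in self.meta]
        if len(set(meta_ids)) != len(meta_ids):
            dup = sorted({i for i in meta_ids if meta_ids.count(i) > 1})
            raise MetadataError(f"duplicate accession id(s) in metadata: {dup}")
        missing = sorted(set(ids) - set(meta_ids))
        if missing:
            raise MetadataError(f"sequence id(s) missing from metadata: {missing}")
        extra = sorted(set(meta_ids) - set(ids))
        if extra:
            raise MetadataError(f"metadata id(s) missing from alignment: {extra}")
        if self.anchor_upstream_bp < self._length:
            raise AlignmentError(
                f"anchor_upstream_bp ({self.anchor_upstream_bp}) < alignment length "
                f"({self._length}): region would overlap the translation start"
            )
        self._meta_by_id = {m.id: m for m in self.meta}

    # -- convenience accessors -------------------------------------------

    @property
    def length(self) -> int:
        """Alignment length L (number of columns)."""
        return self._length

    @property
    def ids(self) -> list[str]:
        return list(self.sequences)

    def meta_of(self, accession_id: str) -> AccessionMeta:
        return self._meta_by_id[accession_id]

    def members(self, group: str) -> list[str]:
        """Ids of accessions in a population group ('wild' or 'cultivated')."""
        return [m.id for m in self.meta if m.group == group]

    def phenotype_of(self, accession_id: str) -> str:
        return self._meta_by_id[accession_id].phenotype

    def subset(self, ids: list[str]) -> "Panel":
        """A new panel restricted to the given accession ids."""
        keep = set(ids)
        return Panel(
            sequences={i: s for i, s in self.sequences.items() if i in keep},
            meta=[m for m in self.meta if m.id in keep],
            anchor_upstream_bp=self.anchor_upstream_bp,
        )


def _sanitize(seq: str, record_id: str) -> str:
    seq = seq.upper()
    bad = set(seq) - VALID_SYMBOLS
    if bad:
        logger.warning(
            "accession %s: symbols %s outside {A,C,G,T,-,N} masked to N",
            record_id,
            "".join(sorted(bad)),
        )
        seq = "".join(c if c in VALID_SYMBOLS else "N" for c in seq)
    return seq


def read_panel(alignment_path, meta_path, anchor_upstream_bp: int) -> Panel:
    """Read an aligned FASTA + metadata TSV into a validated :class:`Panel`.

    The TSV must have a header with at least ``id``, ``group`` and
    ``phenotype`` columns; an ``origin`` column is optional.  Sequence
    symbols are uppercased; symbols outside the alphabet are masked to N
    with a logged warning.
    """
    records = list(SeqIO.parse(str(alignment_path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {alignment_path}")
    sequences = {r.id: _sanitize(str(r.seq), r.id) for r in records}
    if len(sequences) != len(records):
        raise MetadataError("duplicate record id(s) in alignment FASTA")

    table = pd.read_csv(meta_path, sep="\t", dtype=str)
    required = {"id", "group", "phenotype"}
    if not required.issubset(table.columns):
        raise MetadataError(
            f"metadata TSV must have columns {sorted(required)}, got {list(table.columns)}"
        )
    meta = [
        AccessionMeta(
            id=row["id"],
            group=row["group"],
            phenotype=row["phenotype"],
            origin=row.get("origin") if isinstance(row.get("origin"), str) else None,
        )
        for _, row in table.iterrows()
    ]
    return Panel(sequences=sequences, meta=meta, anchor_upstream_bp=anchor_upstream_bp)


def write_panel(panel: Panel, alignment_path, meta_path) -> None:
    """Write a panel back to aligned FASTA + metadata TSV (read_panel inverse)."""
    records = [
        SeqRecord(Seq(seq), id=acc_id, description="") for acc_id, seq in panel.sequences.items()
    ]
    SeqIO.write(records, str(alignment_path), "fasta")
    rows = [
        {"id": m.id, "group": m.group, "phenotype": m.phenotype, "origin": m.origin or ""}
        for m in panel.meta
    ]
    pd.DataFrame(rows).to_csv(meta_path, sep="\t", index=False)


# -- coordinates ---------------------------------------------------------


def column_to_upstream(col: int, panel: Panel) -> int:
    """Map a 0-based alignment column to its bp-upstream-of-ATG position.

    Strictly decreasing in ``col``: column 0 is the most distal position
    (``anchor_upstream_bp``), column L-1 the most proximal.
    """
    if not 0 <= col < panel.length:
        raise IndexError(f"column {col} out of range [0, {panel.length})")
    return panel.anchor_upstream_bp - col


def upstream_to_column(upstream_bp: int, panel: Panel) -> int:
    """Inverse of :func:`column_to_upstream`."""
    col = panel.anchor_upstream_bp - upstream_bp
    if not 0 <= col < panel.length:
        raise IndexError(f"upstream position {upstream_bp} outside the region")
    return col


# -- variant table / VCF writers ----------------------------------------


def write_variant_table(vt, path) -> None:
    """Write a VariantTable as a TSV with one allele column per accession."""
    accession_ids = vt.accession_ids
    rows = []
    for v in vt.variants:
        row = {
            "position_upstream_bp": v.position_upstream_bp,
            "type": v.vtype,
            "ref_allele": v.ref_allele,
            "alt_alleles": ",".join(v.alt_alleles),
        }
        for acc in accession_ids:
            call = v.calls.get(acc)
            row[acc] = call if call is not None else "."
        rows.append(row)
    columns = ["position_upstream_bp", "type", "ref_allele", "alt_alleles"] + list(accession_ids)
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


def read_variant_table(path) -> pd.DataFrame:
    """Read back a variant TSV as a DataFrame ('.' parsed as missing)."""
    df = pd.read_csv(path, sep="\t", dtype={"position_upstream_bp": int})
    return df.replace(".", pd.NA)


def write_vcf(vt, panel: Panel, path) -> None:
    """Write a minimal VCF 4.2 for the variant table.

    The contig is a synthetic forward sequence running distal -> proximal,
    so POS = column + 1 ascends toward the translation start.  The
    bp-upstream coordinate is stored in INFO/UPS.  Indels are left-anchored
    with one base of context; genotypes are haploid (inbred accessions).
    """
    consensus = _consensus(panel)
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID=region,length={panel.length}>",
        '##INFO=<ID=UPS,Number=1,Type=Integer,Description="Position in bp upstream of the translation start">',
        '##INFO=<ID=VT,Number=1,Type=String,Description="Variant type (SNP or INDEL)">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Haploid genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(vt.accession_ids),
    ]
    for v in vt.variants:
        start, end = v.columns
        alleles = [v.ref_allele] + list(v.alt_alleles)
        if v.vtype == "SNP":
            pos = start + 1
            vcf_alleles = alleles
        else:
            # left-anchor with one base of context; degapped allele strings
            if start == 0:
                raise AlignmentError(
                    "cannot left-anchor an indel at alignment column 0 (no context base)"
                )
            anchor = consensus[start - 1]
            vcf_alleles = [anchor + a.replace("-", "") for a in alleles]
            pos = start  # 1-based position of the context column (start - 1)
        ref_field = vcf_alleles[0]
        alt_field = ",".join(vcf_alleles[1:])
        genotypes = []
        for acc in vt.accession_ids:
            call = v.calls.get(acc)
            genotypes.append("." if call is None else str(alleles.index(call)))
        info = f"UPS={v.position_upstream_bp};VT={v.vtype}"
        lines.append(
            f"region\t{pos}\t.\t{ref_field}\t{alt_field}\t.\tPASS\t{info}\tGT\t"
            + "\t".join(genotypes)
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _consensus(panel: Panel) -> str:
    """Per-column majority symbol over the panel (context bases for indels)."""
    out = []
    seqs = list(panel.sequences.values())
    for col in range(panel.length):
        counts: dict[str, int] = {}
        for s in seqs:
            c = s[col]
            if c not in "-N":
                counts[c] = counts.get(c, 0) + 1
        out.append(max(sorted(counts), key=counts.get) if counts else "N")
    return "".join(out)
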