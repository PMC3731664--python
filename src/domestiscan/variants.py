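"""Segregating-site discovery and haplotype collapsing on an aligned panel.

A SNP is a single alignment column with >= 2 distinct non-N symbols and no
gaps.  A multi-base insertion/deletion is represented as one event: a
maximal run of consecutive gap-bearing columns whose gap/non-gap membership
pattern is identical across accessions is merged into a single INDEL
variant whose alleles are the (possibly gapped) substrings over the run.
Accessions sharing an identical allele vector over all variants form one
haplotype; haplotypes are labelled H1, H2, ... by descending size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ConsistencyError
from .panel_io import Panel, column_to_upstream

logger = logging.getLogger(__name__)

#: Accessions missing more than this fraction of calls are dropped from
#: haplotype collapsing (with a warning).
MAX_MISSING_FRACTION = 0.5


@dataclass
class Variant:
    """One segregating site: a SNP column or a merged indel event.

    The reference allele is the majority allele among *wild* accessions
    (the ancestral population), ties broken toward the lexicographically
    smaller allele.  Calls map accession id -> allele string, with ``None``
    for missing (N-containing) calls.
    """

    position_upstream_bp: int
    columns: tuple[int, int]  # half-open 0-based column range
    vtype: str  # "SNP" | "INDEL"
    ref_allele: str
    alt_alleles: list[str]
    calls: dict[str, str | None]
    multiallelic: bool

    @property
    def alleles(self) -> list[str]:
        return [self.ref_allele] + list(self.alt_alleles)

    @property
    def width(self) -> int:
        return self.columns[1] - self.columns[0]


@dataclass
class VariantTable:
    """Variants of one panel ordered distal -> proximal (descending upstream bp)."""

    variants: list[Variant]
    accession_ids: list[str] = field(repr=False)

    def __post_init__(self) -> None:
        positions = [v.position_upstream_bp for v in self.variants]
        if any(p1 <= p2 for p1, p2 in zip(positions, positions[1:])):
            raise ConsistencyError("variants must be strictly ordered distal -> proximal")

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)


@dataclass
class Haplotype:
    """A distinct allele vector over the variant table, with its carriers."""

    label: str
    pattern: tuple[str | None, ...]
    members: list[str]
    n_wild: int
    n_cultivated: int

    @property
    def size(self) -> int:
        return len(self.members)


def _pick_ref(allele_counts_wild: dict[str, int], allele_counts_all: dict[str, int]) -> str:
    """Wild-majority allele; fall back to overall majority if wild is all-missing."""
    source = allele_counts_wild if allele_counts_wild else allele_counts_all
    best = max(source.values())
    return min(a for a, n in source.items() if n == best)


def _make_variant(
    panel: Panel,
    start: int,
    end: int,
    vtype: str,
    calls: dict[str, str | None],
) -> Variant | None:
    wild = set(panel.members("wild"))
    counts_all: dict[str, int] = {}
    counts_wild: dict[str, int] = {}
    for acc, allele in calls.items():
        if allele is None:
            continue
        counts_all[allele] = counts_all.get(allele, 0) + 1
        if acc in wild:
            counts_wild[allele] = counts_wild.get(allele, 0) + 1
    if len(counts_all) < 2:
        return None  # monomorphic (or varying only by N)
    ref = _pick_ref(counts_wild, counts_all)
    alts = sorted(
        (a for a in counts_all if a != ref),
        key=lambda a: (-counts_all[a], a),
    )
    return Variant(
        position_upstream_bp=column_to_upstream(start, panel),
        columns=(start, end),
        vtype=vtype,
        ref_allele=ref,
        alt_alleles=alts,
        calls=calls,
        multiallelic=len(counts_all) > 2,
    )


def segregating_sites(panel: Panel) -> VariantTable:
    """Identify all segregating sites (SNPs and merged indel events).

    Columns that are gapped in every accession, or that vary only by N,
    yield no variant.  Consecutive gap-bearing columns with an identical
    gap-membership pattern merge into one INDEL whose per-accession allele
    is the substring over the run (any N in the substring -> missing call).
    """
    ids = panel.ids
    arr = np.array([list(panel.sequences[i]) for i in ids])
    n, L = arr.shape
    gap = arr == "-"
    any_gap = gap.any(axis=0)
    all_gap = gap.all(axis=0)

    variants: list[Variant] = []
    col = 0
    while col < L:
        if all_gap[col]:
            col += 1
            continue
        if any_gap[col]:
            # extend a maximal run with identical gap membership, skipping
            # nothing: run breaks when membership changes or gaps end
            pattern = gap[:, col]
            end = col + 1
            while (
                end < L
                and any_gap[end]
                and not all_gap[end]
                and np.array_equal(gap[:, end], pattern)
            ):
                end += 1
            calls: dict[str, str | None] = {}
            for k, acc in enumerate(ids):
                substr = "".join(arr[k, col:end])
                calls[acc] = None if "N" in substr else substr
            v = _make_variant(panel, col, end, "INDEL", calls)
            if v is not None:
                variants.append(v)
            col = end
            continue
        # plain column: SNP candidate
        symbols = arr[:, col]
        calls = {acc: (None if s == "N" else s) for acc, s in zip(ids, symbols)}
        v = _make_variant(panel, col, col + 1, "SNP", calls)
        if v is not None:
            variants.append(v)
        col += 1
    return VariantTable(variants=variants, accession_ids=ids)


def collapse_haplotypes(vt: VariantTable, panel: Panel) -> list[Haplotype]:
    """Group accessions by exact equality of their allele vectors.

    A missing call never equals a concrete allele, so an accession with
    missing data only joins a haplotype whose pattern is identical
    *including* the missing slots.  Accessions missing more than half of
    their calls are dropped with a warning.  Labels are assigned by
    descending member count, ties by first appearance in panel order.
    """
    if set(vt.accession_ids) != set(panel.ids):
        raise ConsistencyError("variant table and panel describe different accessions")
    wild = set(panel.members("wild"))
    patterns: dict[tuple, list[str]] = {}
    order: list[tuple] = []
    n_var = len(vt.variants)
    for acc in panel.ids:
        pattern = tuple(v.calls.get(acc) for v in vt.variants)
        n_missing = sum(1 for a in pattern if a is None)
        if n_var and n_missing / n_var > MAX_MISSING_FRACTION:
            logger.warning(
                "accession %s missing %d/%d variant calls; dropped from haplotype analysis",
                acc,
                n_missing,
                n_var,
            )
            continue
        if pattern not in patterns:
            patterns[pattern] = []
            order.append(pattern)
        patterns[pattern].append(acc)
    ranked = sorted(order, key=lambda p: (-len(patterns[p]), order.index(p)))
    haplotypes = []
    for rank, pattern in enumerate(ranked, start=1):
        members = patterns[pattern]
        n_w = sum(1 for m in members if m in wild)
        haplotypes.append(
            Haplotype(
                label=f"H{rank}",
                pattern=pattern,
                members=members,
                n_wild=n_w,
                n_cultivated=len(members) - n_w,
            )
        )
    return haplotypes


def write_haplotype_table(haplotypes: list[Haplotype], path) -> None:
    """Write haplotypes as TSV (label, pattern, counts, members)."""
    import pandas as pd

    rows = [
        {
            "label": h.label,
            "pattern": "/".join("." if a is None else a for a in h.pattern),
            "n_wild": h.n_wild,
            "n_cultivated": h.n_cultivated,
            "members": ",".join(h.members),
        }
        for h in haplotypes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
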