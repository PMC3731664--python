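"""Bisulfite clone-sequencing analysis of a promoter region.

Bisulfite treatment converts unmethylated cytosine to uracil, which reads
as T after PCR and Sanger sequencing of cloned fragments; methylated C is
protected and reads as C.  At every cytosine of the reference promoter a
clone is therefore called methylated (C), unmethylated (T) or ambiguous
(any other symbol).  Only the converted top strand is modeled, so
reference G positions (bottom-strand cytosines) are ignored.  Clones are
assumed gapless and pre-aligned to the reference (Sanger reads of one PCR
fragment).  Percent methylation at a site is 100 * n_meth / (n_meth +
n_unmeth); ambiguous calls are excluded.

Calling never corrects for incomplete bisulfite conversion; instead a
per-clone QC (the apparent methylation rate outside CpG context, which is
near zero in plant promoters only if conversion is complete) is available
via :func:`conversion_qc`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .errors import AlignmentError, DomestiscanError
from .assoc import fisher_exact_two_sided

logger = logging.getLogger(__name__)

MIN_CLONES = 30  # standard minimum clone count for stable percent estimates

METHYLATED, UNMETHYLATED, AMBIGUOUS = "M", "U", "?"


@dataclass
class MethylationSite:
    """Summary of one reference cytosine over a clone set."""

    position: int  # 0-based on the reference promoter
    context: str  # CpG | CHG | CHH
    n_methylated: int
    n_unmethylated: int
    n_ambiguous: int

    @property
    def percent(self) -> float:
        covered = self.n_methylated + self.n_unmethylated
        if covered < 1:
            raise DomestiscanError(
                f"site {self.position}: percent undefined with no unambiguous calls"
            )
        return 100.0 * self.n_methylated / covered


@dataclass
class CloneSet:
    """Sequenced clones of one bisulfite PCR fragment, aligned to a reference."""

    reference: str
    clones: list[str]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.clones:
            raise DomestiscanError("clone set is empty")
        bad = [i for i, c in enumerate(self.clones) if len(c) != len(self.reference)]
        if bad:
            raise AlignmentError(
                f"clone(s) {bad} differ in length from the reference"
            )
        self.reference = self.reference.upper()
        self.clones = [c.upper() for c in self.clones]


def call_clone(clone: str, reference: str) -> dict[int, str]:
    """Per-cytosine methylation state of one clone.

    Returns {reference C position: 'M' | 'U' | '?'}: retained C is
    methylated, converted C (read T) is unmethylated, anything else is
    ambiguous.  Non-C reference positions are ignored.
    """
    if len(clone) != len(reference):
        raise AlignmentError("clone and reference lengths differ")
    clone = clone.upper()
    states = {}
    for pos, ref_base in enumerate(reference.upper()):
        if ref_base != "C":
            continue
        base = clone[pos]
        if base == "C":
            states[pos] = METHYLATED
        elif base == "T":
            states[pos] = UNMETHYLATED
        else:
            states[pos] = AMBIGUOUS
    return states


def cytosine_context(reference: str, pos: int) -> str:
    """Sequence context of a reference cytosine: CpG, CHG or CHH (H = A/C/T).

    Positions too close to the reference end to resolve default to CHH.
    """
    L = len(reference)
    if pos + 1 < L and reference[pos + 1] == "G":
        return "CpG"
    if pos + 2 < L and reference[pos + 1] in "ACT" and reference[pos + 2] == "G":
        return "CHG"
    return "CHH"


def site_table(cloneset: CloneSet) -> list[MethylationSite]:
    """Aggregate per-clone calls into per-site methylation summaries."""
    if len(cloneset.clones) < MIN_CLONES:
        logger.warning(
            "clone set %s has %d clones (< %d); percent estimates will be noisy",
            cloneset.label or "<unnamed>",
            len(cloneset.clones),
            MIN_CLONES,
        )
    ref = cloneset.reference
    positions = [i for i, b in enumerate(ref) if b == "C"]
    counts = {p: {METHYLATED: 0, UNMETHYLATED: 0, AMBIGUOUS: 0} for p in positions}
    for clone in cloneset.clones:
        for pos, state in call_clone(clone, ref).items():
            counts[pos][state] += 1
    return [
        MethylationSite(
            position=p,
            context=cytosine_context(ref, p),
            n_methylated=counts[p][METHYLATED],
            n_unmethylated=counts[p][UNMETHYLATED],
            n_ambiguous=counts[p][AMBIGUOUS],
        )
        for p in positions
    ]


def compare_sites(site_a: MethylationSite, site_b: MethylationSite) -> float:
    """Two-sided Fisher exact p for differential methylation at one site
    between two samples (2x2: methylated/unmethylated x sample)."""
    for s in (site_a, site_b):
        if s.n_methylated + s.n_unmethylated < 1:
            raise DomestiscanError("site with no unambiguous calls")
    return fisher_exact_two_sided(
        site_a.n_methylated, site_a.n_unmethylated,
        site_b.n_methylated, site_b.n_unmethylated,
    )


def conversion_qc(cloneset: CloneSet) -> pd.DataFrame:
    """Per-clone apparent non-CpG methylation rate (conversion-failure proxy)."""
    ref = cloneset.reference
    non_cpg = [
        i for i, b in enumerate(ref)
        if b == "C" and cytosine_context(ref, i) != "CpG"
    ]
    rows = []
    for k, clone in enumerate(cloneset.clones):
        states = call_clone(clone, ref)
        meth = sum(1 for p in non_cpg if states[p] == METHYLATED)
        total = sum(1 for p in non_cpg if states[p] != AMBIGUOUS)
        rows.append(
            {
                "clone": k,
                "non_cpg_methylated": meth,
                "non_cpg_covered": total,
                "rate": meth / total if total else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def site_table_tsv(sites: list[MethylationSite], path, labels: dict[int, str] | None = None) -> None:
    """Write a site table as TSV; ``labels`` optionally names positions
    (e.g. {240: 'Cyt_241'})."""
    rows = []
    for s in sites:
        covered = s.n_methylated + s.n_unmethylated
        rows.append(
            {
                "position": s.position,
                "label": (labels or {}).get(s.position, ""),
                "context": s.context,
                "n_methylated": s.n_methylated,
                "n_unmethylated": s.n_unmethylated,
                "n_ambiguous": s.n_ambiguous,
                "percent": s.percent if covered else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
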