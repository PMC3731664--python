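"""F2 dominant-trait genetics: segregation test and interval delimitation.

An F2 population from a cross between a donor (spread panicle, dominant)
and a recurrent (compact panicle) parent segregates 3:1 for the dominant
trait if a single locus controls it.  Compact plants are homozygous
recurrent (A) at the functional mutation (FM), which makes them fully
informative for fine mapping: any marker where a compact plant carries a
donor allele (H or B call) must be separated from the FM by at least one
recombination.  Graphical genotyping intersects, over all such plants, the
chromosome segments where an A genotype is consistent with the marker
calls; the FM interval is that intersection snapped outward to the nearest
flanking markers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .errors import ConfigError, DomestiscanError, InconsistencyError

#: Genotype codes: recurrent homozygote, heterozygote, donor homozygote, missing.
GENO_CODES = {"A": 0, "H": 1, "B": 2, "-": -1, ".": -1}
CODE_TO_GENO = {0: "A", 1: "H", 2: "B", -1: "."}


@dataclass(frozen=True)
class Marker:
    name: str
    physical_bp: int


@dataclass
class F2Table:
    """Per-plant marker genotypes and phenotypes for an F2 population.

    ``genotypes`` is an (n_plants, n_markers) int8 array with codes
    0 = A (recurrent homozygous), 1 = H, 2 = B (donor homozygous),
    -1 = missing.  Marker physical positions must strictly increase.
    """

    markers: list[Marker]
    plant_ids: list[str]
    phenotypes: list[str]  # "spread" | "compact"
    genotypes: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        pos = [m.physical_bp for m in self.markers]
        if any(p2 <= p1 for p1, p2 in zip(pos, pos[1:])):
            raise ConfigError("marker physical positions must strictly increase")
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.plant_ids), len(self.markers)):
            raise ConfigError("genotype matrix shape does not match plants x markers")
        if len(self.phenotypes) != len(self.plant_ids):
            raise ConfigError("one phenotype required per plant")
        bad = set(self.phenotypes) - {"spread", "compact"}
        if bad:
            raise ConfigError(f"unknown phenotype value(s): {sorted(bad)}")

    @property
    def n_plants(self) -> int:
        return len(self.plant_ids)

    def marker_index(self, name: str) -> int:
        for k, m in enumerate(self.markers):
            if m.name == name:
                return k
        raise KeyError(f"unknown marker {name!r}")


@dataclass
class MapInterval:
    """A marker-delimited interval containing the functional mutation."""

    left_marker: str
    right_marker: str
    span_bp: int
    n_informative: int


def segregation_test(n_spread: int, n_compact: int) -> tuple[float, float]:
    """Chi-square goodness of fit of observed counts to the 3:1 dominant model.

    1 df, no continuity correction; p from the chi-square survival function.
    """
    if n_spread < 0 or n_compact < 0:
        raise DomestiscanError("counts must be non-negative")
    n = n_spread + n_compact
    if n < 1:
        raise DomestiscanError("need at least one plant")
    e_spread, e_compact = 0.75 * n, 0.25 * n
    stat = (n_spread - e_spread) ** 2 / e_spread + (n_compact - e_compact) ** 2 / e_compact
    return float(stat), float(chi2.sf(stat, df=1))


def informative_recombinants(f2: F2Table, marker: str) -> int:
    """Count recombinant gametes between a marker and the FM.

    Under the dominant-donor model a compact plant is A/A at the FM, so an
    H call at the marker is one recombinant gamete and a B call is two.
    A spread plant's FM genotype is ambiguous (H or B); only a marker-A
    call certifies at least one recombinant gamete, counted as 1 (a lower
    bound).  Missing calls contribute 0.
    """
    k = f2.marker_index(marker)
    calls = f2.genotypes[:, k]
    count = 0
    for call, pheno in zip(calls, f2.phenotypes):
        if call == -1:
            continue
        if pheno == "compact":
            count += int(call)  # H -> 1, B -> 2, A -> 0
        elif call == 0:
            count += 1
    return count


def _allowed_intervals(positions: list[int], calls: np.ndarray) -> list[tuple[float, float]]:
    """Closed intervals where an A genotype at the FM is consistent.

    Breakpoints sit at midpoints between adjacent genotyped markers with
    differing A/non-A status; beyond the outermost genotyped markers the
    chromosome is unconstrained (a distal breakpoint cannot be excluded).
    """
    typed = [(p, c) for p, c in zip(positions, calls) if c != -1]
    if not typed:
        return [(-math.inf, math.inf)]
    is_a = [c == 0 for _, c in typed]
    if all(is_a):
        return [(-math.inf, math.inf)]
    intervals: list[tuple[float, float]] = []
    if not any(is_a):
        # FM cannot sit at any genotyped marker; only the flanks remain
        return [(-math.inf, typed[0][0] - 1), (typed[-1][0] + 1, math.inf)]
    k = 0
    m = len(typed)
    while k < m:
        if not is_a[k]:
            k += 1
            continue
        run_start = k
        while k < m and is_a[k]:
            k += 1
        run_end = k - 1
        left = (
            -math.inf
            if run_start == 0
            else (typed[run_start - 1][0] + typed[run_start][0]) / 2.0
        )
        right = (
            math.inf
            if run_end == m - 1
            else (typed[run_end][0] + typed[run_end + 1][0]) / 2.0
        )
        intervals.append((left, right))
    return intervals


def _intersect(sets_a, sets_b):
    out = []
    for a0, a1 in sets_a:
        for b0, b1 in sets_b:
            lo, hi = max(a0, b0), min(a1, b1)
            if lo <= hi:
                out.append((lo, hi))
    return out


def delimit_interval(f2: F2Table) -> MapInterval:
    """Delimit the FM interval by graphical-genotype intersection.

    Only compact plants constrain the interval; plants with at least one
    non-A, non-missing call are the informative ones.  An empty
    intersection raises :class:`InconsistencyError` — a phenotyping or
    genotyping error, or a trait not under single-dominant-locus control.
    Double recombinants between adjacent markers are assumed absent.
    """
    if len(f2.markers) < 2:
        raise DomestiscanError("need >= 2 markers")
    if f2.n_plants < 1:
        raise DomestiscanError("need >= 1 plant")
    positions = [m.physical_bp for m in f2.markers]
    allowed = [(-math.inf, math.inf)]
    n_informative = 0
    for i, pheno in enumerate(f2.phenotypes):
        if pheno != "compact":
            continue
        calls = f2.genotypes[i]
        if not ((calls > 0).any()):
            continue  # all A or missing: unconstraining
        n_informative += 1
        allowed = _intersect(allowed, _allowed_intervals(positions, calls))
        if not allowed:
            raise InconsistencyError(
                "no chromosome segment is consistent with all compact plants; "
                "check phenotyping/genotyping, or the trait may be controlled "
                "by more than one locus (e.g. two complementary dominant genes)"
            )
    hull_lo = min(a for a, _ in allowed)
    hull_hi = max(b for _, b in allowed)
    left_candidates = [m for m in f2.markers if m.physical_bp <= hull_lo]
    right_candidates = [m for m in f2.markers if m.physical_bp >= hull_hi]
    left = left_candidates[-1] if left_candidates else f2.markers[0]
    right = right_candidates[0] if right_candidates else f2.markers[-1]
    if left.physical_bp >= right.physical_bp:
        # point interval at a marker: widen to the adjacent markers
        idx = f2.marker_index(left.name)
        left = f2.markers[max(idx - 1, 0)]
        right = f2.markers[min(idx + 1, len(f2.markers) - 1)]
    return MapInterval(
        left_marker=left.name,
        right_marker=right.name,
        span_bp=right.physical_bp - left.physical_bp,
        n_informative=n_informative,
    )


# -- TSV I/O -------------------------------------------------------------


def read_f2_table(genotype_path, marker_path) -> F2Table:
    """Read plant genotypes (id, phenotype, one column per marker) and a
    marker map (name, physical_bp) from TSV files."""
    mk = pd.read_csv(marker_path, sep="\t")
    markers = [Marker(str(r["name"]), int(r["physical_bp"])) for _, r in mk.iterrows()]
    gt = pd.read_csv(genotype_path, sep="\t", dtype=str)
    names = [m.name for m in markers]
    missing_cols = [n for n in names if n not in gt.columns]
    if missing_cols:
        raise ConfigError(f"genotype table lacks marker column(s): {missing_cols}")
    geno = np.array(
        [[GENO_CODES.get(gt.loc[i, n], -1) for n in names] for i in gt.index],
        dtype=np.int8,
    )
    return F2Table(
        markers=markers,
        plant_ids=gt["id"].tolist(),
        phenotypes=gt["phenotype"].tolist(),
        genotypes=geno,
    )


def write_f2_table(f2: F2Table, genotype_path, marker_path) -> None:
    pd.DataFrame(
        [{"name": m.name, "physical_bp": m.physical_bp} for m in f2.markers]
    ).to_csv(marker_path, sep="\t", index=False)
    rows = []
    for i, pid in enumerate(f2.plant_ids):
        row = {"id": pid, "phenotype": f2.phenotypes[i]}
        for k, m in enumerate(f2.markers):
            row[m.name] = CODE_TO_GENO[int(f2.genotypes[i, k])]
        rows.append(row)
    pd.DataFrame(rows).to_csv(genotype_path, sep="\t", index=False)
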