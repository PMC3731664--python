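"""Synthetic-data generators for every pipeline stage.

The generators reproduce the statistical structure the analyses assume,
with closed-form expectations that make exact tests possible:

* ``sim_panel`` — a star-genealogy accession panel after a domestication
  sweep: wild accessions are independent per-site mutants of a shared
  ancestor (so E[pi] ~= 2 mu for small mu), while all cultivars descend
  from a single founder haplotype carrying the derived causal allele, a
  set of fully linked fixed differences and an optional multi-bp deletion.
  The causal site separates the groups completely by construction.
* ``paper_like_panel`` — a preset with 21 wild / 158 cultivated
  accessions, exactly 12 SNPs + one 6-bp indel, many wild haplotypes and
  an 8/150 split of the cultivars into two haplotypes.
* ``sim_f2`` — an F2 population from a donor x recurrent cross; gametes
  are Markov walks along the marker map with Haldane recombination
  fractions; the trait is dominant at the FM locus (3:1 segregation).
* ``sim_bisulfite`` — clone sets with per-site methylation rates and a
  conversion-efficiency parameter.
* ``sim_ct`` — qPCR CT tables with known fold changes and Gaussian noise.
* ``sim_tree_distances`` — random binary trees with their exact (additive)
  path-distance matrices.

All generators take an explicit integer seed and are bit-reproducible;
there is no hidden global random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .errors import ConfigError
from .finemap import F2Table, Marker
from .methylome import CloneSet
from .panel_io import AccessionMeta, Panel
from .qpcr import CtRecord

BASES = np.array(list("ACGT"))


# ----------------------------------------------------------------------
# accession panel
# ----------------------------------------------------------------------


@dataclass
class PanelSimConfig:
    """Star-genealogy panel simulation after a domestication sweep.

    ``mu_wild`` / ``mu_cult`` are per-site tip mutation probabilities
    (each accession mutates independently from its founder); the causal
    column, the ``n_linked_fixed`` linked columns and the optional indel
    columns are protected from background mutation so the sweep structure
    is exact.
    """

    n_wild: int = 21
    n_cultivated: int = 158
    L: int = 3300
    mu_wild: float = 0.005
    mu_cult: float = 2e-4
    causal_col: int = 2300
    n_linked_fixed: int = 3
    indel: tuple[int, int] | None = (1200, 6)  # (start column, length)
    #: probability that a wild accession also carries the derived allele at
    #: a linked site (or the deletion): keeps those sites in high but
    #: incomplete LD with the causal site, so the causal site is the unique
    #: strongest association signal (its separation stays complete).
    wild_linked_carrier_rate: float = 0.1
    anchor_upstream_bp: int = 13300
    seed: int = 0

    def __post_init__(self) -> None:
        for name, mu in (("mu_wild", self.mu_wild), ("mu_cult", self.mu_cult)):
            if not 0 <= mu < 0.5:
                raise ConfigError(f"{name} must be in [0, 0.5), got {mu}")
        if not 0 <= self.causal_col < self.L:
            raise ConfigError("causal_col outside the region")
        if self.indel is not None:
            start, length = self.indel
            if length < 1 or start < 1 or start + length > self.L:
                raise ConfigError("indel must fit inside the region with left context")
        if self.n_wild < 1 or self.n_cultivated < 1:
            raise ConfigError("both groups need >= 1 accession")
        if not 0 <= self.wild_linked_carrier_rate < 1:
            raise ConfigError("wild_linked_carrier_rate must be in [0, 1)")
        if self.anchor_upstream_bp < self.L:
            raise ConfigError("anchor_upstream_bp must be >= L")


def _mutate(rng: np.random.Generator, seq: np.ndarray, mu: float, frozen: np.ndarray) -> np.ndarray:
    """Independent per-site mutation at rate mu, never touching frozen columns."""
    out = seq.copy()
    hit = (rng.random(seq.size) < mu) & ~frozen
    for col in np.flatnonzero(hit):
        choices = BASES[BASES != out[col]]
        out[col] = rng.choice(choices)
    return out


def sim_panel(cfg: PanelSimConfig) -> Panel:
    """Simulate an aligned accession panel with a planted causal site.

    Wild accessions carry the ancestral causal allele, cultivars the
    derived one — complete separation, as observed in a hard sweep.  With
    ``mu_cult = 0`` every cultivar is identical to the founder, giving one
    cultivar haplotype and pi = 0.
    """
    rng = np.random.default_rng(cfg.seed)
    ancestor = rng.choice(BASES, size=cfg.L)

    frozen = np.zeros(cfg.L, dtype=bool)
    frozen[cfg.causal_col] = True
    linked_pool = [c for c in range(cfg.L) if not frozen[c]]
    linked_cols = sorted(
        rng.choice(linked_pool, size=cfg.n_linked_fixed, replace=False).tolist()
    ) if cfg.n_linked_fixed else []
    frozen[linked_cols] = True
    indel_cols: list[int] = []
    if cfg.indel is not None:
        start, length = cfg.indel
        indel_cols = list(range(start, start + length))
        frozen[indel_cols] = True

    founder = ancestor.copy()
    derived = {}
    for col in [cfg.causal_col] + linked_cols:
        derived[col] = rng.choice(BASES[BASES != ancestor[col]])
        founder[col] = derived[col]
    if indel_cols:
        founder[indel_cols] = "-"  # cultivar founder carries the deletion

    def _wild_carriers() -> set[int]:
        # low-frequency wild carriers, at least one, so the variant truly
        # segregates in the wild group (LD with the causal site < 1)
        carriers = set(np.flatnonzero(rng.random(cfg.n_wild) < cfg.wild_linked_carrier_rate))
        if not carriers and cfg.n_wild > 1:
            carriers = {int(rng.integers(cfg.n_wild))}
        return carriers

    linked_carriers = {col: _wild_carriers() for col in linked_cols}
    indel_carriers = _wild_carriers() if indel_cols else set()

    sequences: dict[str, str] = {}
    meta: list[AccessionMeta] = []
    for k in range(cfg.n_wild):
        acc = f"W{k + 1:03d}"
        seq = _mutate(rng, ancestor, cfg.mu_wild, frozen)
        for col in linked_cols:
            if k in linked_carriers[col]:
                seq[col] = derived[col]
        if k in indel_carriers:
            seq[indel_cols] = "-"
        sequences[acc] = "".join(seq)
        meta.append(AccessionMeta(id=acc, group="wild", phenotype="spread"))
    for k in range(cfg.n_cultivated):
        acc = f"C{k + 1:03d}"
        sequences[acc] = "".join(_mutate(rng, founder, cfg.mu_cult, frozen))
        meta.append(AccessionMeta(id=acc, group="cultivated", phenotype="compact"))
    return Panel(sequences=sequences, meta=meta, anchor_upstream_bp=cfg.anchor_upstream_bp)


def paper_like_panel(seed: int = 0) -> tuple[Panel, dict]:
    """Preset panel mirroring the published structure at desk scale.

    21 wild + 158 cultivated accessions over a 3.3-kb region with exactly
    13 variants: one causal SNP with complete wild/cultivar separation,
    three cultivar-fixed SNPs in complete LD with it, eight SNPs
    polymorphic among wild accessions only (tuned so the 21 wild
    accessions fall into many haplotypes), and one 6-bp deletion fixed in
    cultivars.  Eight cultivars carry a derived allele at one of the free
    SNPs, splitting the cultivars into a 150/8 pair of haplotypes.

    Returns (panel, truth) where ``truth`` records the planted columns.
    """
    rng = np.random.default_rng(seed)
    L, anchor = 3300, 13300
    ancestor = rng.choice(BASES, size=L)

    causal_col = 2300  # maps to 11,000 bp upstream with anchor 13,300
    indel_start, indel_len = 1200, 6
    indel_cols = list(range(indel_start, indel_start + indel_len))
    reserved = {causal_col, *indel_cols}
    pool = [c for c in range(L) if c not in reserved]
    picked = rng.choice(pool, size=11, replace=False)
    linked_cols = sorted(int(c) for c in picked[:3])
    free_cols = sorted(int(c) for c in picked[3:])
    split_col = free_cols[0]  # distinguishes the two cultivar haplotypes

    def derived(col: int) -> str:
        return str(rng.choice(BASES[BASES != ancestor[col]]))

    derived_alleles = {c: derived(c) for c in [causal_col, *linked_cols, *free_cols]}

    sequences: dict[str, str] = {}
    meta: list[AccessionMeta] = []
    # two wild carriers of each linked-site derived allele and of the
    # deletion keep those variants in high but incomplete LD with the
    # causal site (medium association signals, r^2 > 0.6 but < 1)
    linked_carriers = {c: set(rng.choice(21, size=2, replace=False).tolist()) for c in linked_cols}
    indel_carriers = set(rng.choice(21, size=2, replace=False).tolist())
    for k in range(21):
        seq = ancestor.copy()
        # each wild accession independently carries derived alleles at the
        # free sites; 0.35 per site spreads 21 accessions over many patterns
        for col in free_cols:
            if rng.random() < 0.35:
                seq[col] = derived_alleles[col]
        for col in linked_cols:
            if k in linked_carriers[col]:
                seq[col] = derived_alleles[col]
        if k in indel_carriers:
            seq[indel_cols] = "-"
        acc = f"W{k + 1:03d}"
        sequences[acc] = "".join(seq)
        meta.append(AccessionMeta(id=acc, group="wild", phenotype="spread"))

    founder = ancestor.copy()
    for col in [causal_col, *linked_cols]:
        founder[col] = derived_alleles[col]
    founder[indel_cols] = "-"
    minor = founder.copy()
    minor[split_col] = derived_alleles[split_col]
    for k in range(158):
        acc = f"C{k + 1:03d}"
        seq = minor if k < 8 else founder  # 8 minor-haplotype cultivars
        sequences[acc] = "".join(seq)
        meta.append(AccessionMeta(id=acc, group="cultivated", phenotype="compact"))

    panel = Panel(sequences=sequences, meta=meta, anchor_upstream_bp=anchor)
    truth = {
        "causal_col": causal_col,
        "causal_upstream_bp": anchor - causal_col,
        "linked_cols": linked_cols,
        "free_cols": free_cols,
        "split_col": split_col,
        "indel": (indel_start, indel_len),
    }
    return panel, truth


# ----------------------------------------------------------------------
# F2 population
# ----------------------------------------------------------------------


@dataclass
class F2SimConfig:
    """F2 simulation along a marker map with a dominant FM locus.

    ``markers`` is a list of (name, cM, physical bp) with both orders
    agreeing; ``fm_cm`` is the FM's genetic position and ``fm_bp`` its
    physical position (interpolated from flanking markers when omitted).
    """

    n_plants: int
    markers: list[tuple[str, float, int]]
    fm_cm: float
    fm_bp: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_plants < 1:
            raise ConfigError("n_plants must be >= 1")
        cms = [m[1] for m in self.markers]
        bps = [m[2] for m in self.markers]
        if sorted(cms) != cms or sorted(bps) != bps:
            raise ConfigError("marker genetic and physical orders must agree (ascending)")
        if len(self.markers) < 2:
            raise ConfigError("need >= 2 markers")
        if self.fm_bp is None:
            self.fm_bp = self._interpolate_bp(self.fm_cm)

    def _interpolate_bp(self, cm: float) -> int:
        ms = self.markers
        if cm <= ms[0][1]:
            return ms[0][2]
        if cm >= ms[-1][1]:
            return ms[-1][2]
        for (n1, c1, b1), (n2, c2, b2) in zip(ms, ms[1:]):
            if c1 <= cm <= c2:
                if c2 == c1:
                    return b1
                return int(round(b1 + (cm - c1) / (c2 - c1) * (b2 - b1)))
        raise ConfigError("FM genetic position outside the map")


def haldane_r(d_cm: float) -> float:
    """Haldane map function: recombination fraction for a distance in cM."""
    return 0.5 * (1.0 - math.exp(-2.0 * d_cm / 100.0))


def sim_f2(cfg: F2SimConfig) -> F2Table:
    """Simulate an F2 population segregating for a dominant trait.

    Each plant receives two independent gametes; each gamete is a Markov
    walk over the loci (markers + FM in cM order) switching parental phase
    with Haldane's recombination fraction between adjacent loci.  The
    phenotype is spread iff the plant carries >= 1 donor allele at the FM
    (dominance), so phenotypes segregate 3:1 in expectation.
    """
    rng = np.random.default_rng(cfg.seed)
    loci = sorted(
        [(name, cm) for name, cm, _ in cfg.markers] + [("__FM__", cfg.fm_cm)],
        key=lambda t: (t[1], t[0] != "__FM__"),
    )
    names = [n for n, _ in loci]
    cms = np.array([c for _, c in loci])
    fm_idx = names.index("__FM__")
    rs = np.array([haldane_r(d) for d in np.diff(cms)])

    n_gametes = 2 * cfg.n_plants
    start = rng.random(n_gametes) < 0.5  # True = donor phase at first locus
    switches = rng.random((n_gametes, len(rs))) < rs
    phase = np.empty((n_gametes, len(loci)), dtype=bool)
    phase[:, 0] = start
    phase[:, 1:] = start[:, None] ^ (np.cumsum(switches, axis=1) % 2).astype(bool)

    g1 = phase[: cfg.n_plants]
    g2 = phase[cfg.n_plants:]
    donor_count = g1.astype(np.int8) + g2.astype(np.int8)  # 0=A, 1=H, 2=B

    spread = donor_count[:, fm_idx] >= 1
    marker_idx = [k for k in range(len(loci)) if k != fm_idx]
    marker_objs = [Marker(name, bp) for name, _, bp in cfg.markers]
    return F2Table(
        markers=marker_objs,
        plant_ids=[f"P{i + 1}" for i in range(cfg.n_plants)],
        phenotypes=["spread" if s else "compact" for s in spread],
        genotypes=donor_count[:, marker_idx],
    )


# ----------------------------------------------------------------------
# bisulfite clones
# ----------------------------------------------------------------------


def sim_bisulfite(
    reference: str,
    site_rates: dict[int, float],
    n_clones: int,
    conversion: float = 0.995,
    seed: int = 0,
    label: str = "sim",
) -> CloneSet:
    """Simulate bisulfite-converted clone sequences of a reference.

    At every reference C a clone is methylated with the site's rate
    (default 0): methylated C is always retained; an unmethylated C reads
    T with probability ``conversion`` and is otherwise retained as C
    (incomplete conversion).  Non-C positions are copied unchanged.
    """
    if not 0.0 < conversion <= 1.0:
        raise ConfigError("conversion must be in (0, 1]")
    ref = reference.upper()
    for pos, rate in site_rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ConfigError(f"rate at {pos} outside [0, 1]")
        if pos < 0 or pos >= len(ref) or ref[pos] != "C":
            raise ConfigError(f"site {pos} is not a reference cytosine")
    if n_clones < 1:
        raise ConfigError("n_clones must be >= 1")
    rng = np.random.default_rng(seed)
    c_positions = [i for i, b in enumerate(ref) if b == "C"]
    clones = []
    for _ in range(n_clones):
        seq = list(ref)
        for pos in c_positions:
            if rng.random() < site_rates.get(pos, 0.0):
                continue  # methylated: protected from conversion
            if rng.random() < conversion:
                seq[pos] = "T"
        clones.append("".join(seq))
    return CloneSet(reference=ref, clones=clones, label=label)


def random_promoter(length: int = 1400, seed: int = 0, gc: float = 0.45) -> str:
    """A random promoter-scale reference sequence (no gaps)."""
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(BASES, size=length, p=probs))


# ----------------------------------------------------------------------
# qPCR
# ----------------------------------------------------------------------


def sim_ct(
    true_rq: dict[str, float],
    base_ct: float = 20.0,
    noise_sd: float = 0.2,
    n_reps: int = 3,
    seed: int = 0,
    sample: str = "sim",
    calibrator_tissue: str | None = None,
) -> list[CtRecord]:
    """Simulate CT records with known fold changes per tissue.

    Reference-gene CTs are ``base_ct`` + Gaussian noise; target CTs are
    shifted by -log2(fold change), so the ddCT pipeline recovers
    ``true_rq`` exactly at zero noise when calibrated against the tissue
    with fold change 1 (``calibrator_tissue`` defaults to the first).
    """
    if n_reps < 1:
        raise ConfigError("n_reps must be >= 1")
    for tissue, rq in true_rq.items():
        if rq <= 0:
            raise ConfigError(f"fold change for {tissue} must be > 0")
    rng = np.random.default_rng(seed)
    records = []
    for tissue, rq in true_rq.items():
        ref_cts = base_ct + rng.normal(0, noise_sd, size=n_reps)
        target_cts = base_ct - math.log2(rq) + rng.normal(0, noise_sd, size=n_reps)
        records.append(CtRecord(sample, tissue, "reference", [float(x) for x in ref_cts]))
        records.append(CtRecord(sample, tissue, "target", [float(x) for x in target_cts]))
    return records


# ----------------------------------------------------------------------
# trees
# ----------------------------------------------------------------------


def sim_tree_distances(n_leaves: int, seed: int = 0) -> tuple[TreeNode, DistanceMatrix]:
    """Random binary tree with its exact path-distance matrix.

    Branch lengths are uniform on [0.1, 1.0], so the matrix is strictly
    additive and neighbor joining must recover the topology exactly.
    """
    if n_leaves < 3:
        raise ConfigError("need >= 3 leaves")
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=f"L{k + 1}") for k in range(n_leaves)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a = nodes.pop(j)
        b = nodes.pop(i)
        a.length = float(rng.uniform(0.1, 1.0))
        b.length = float(rng.uniform(0.1, 1.0))
        nodes.append(TreeNode(children=[b, a]))
    for node in nodes:
        node.length = float(rng.uniform(0.1, 1.0))
    tree = TreeNode(children=nodes)
    dm = tree.tip_tip_distances()
    ids = sorted(dm.ids)
    return tree, dm.filter(ids)
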