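"""Relative expression quantification by the 2^-ddCT method.

For each replicate, the target gene's CT is normalised by the reference
gene (dCT = CT_target - CT_reference), the calibrator sample's dCT is
subtracted (ddCT), and the fold change is 2^-ddCT, assuming perfect
amplification efficiency (doubling per cycle).  Replicates are paired by
index (technical runs); an unpaired mode using mean dCT per sample is
available for designs without run pairing.
"""

from __future__ import annotations

import logging
import math
import statistics
from dataclasses import dataclass

import pandas as pd

from .errors import DomestiscanError

logger = logging.getLogger(__name__)


@dataclass
class CtRecord:
    """Replicate CT values for one (sample, tissue, gene) combination."""

    sample: str
    tissue: str
    gene: str  # "target" | "reference"
    cts: list[float]

    def __post_init__(self) -> None:
        if not self.cts:
            raise DomestiscanError("CtRecord needs >= 1 replicate")
        if any(not 0 < ct < 50 for ct in self.cts):
            raise DomestiscanError(f"CT values outside (0, 50): {self.cts}")


def ddct(
    target_sample: CtRecord,
    ref_sample: CtRecord,
    target_calibrator: CtRecord,
    ref_calibrator: CtRecord,
    paired: bool = True,
) -> tuple[float, float, list[float]]:
    """Fold change of the sample relative to the calibrator (2^-ddCT).

    Returns (mean fold change, sample SD with n-1 denominator, per-replicate
    fold changes).  In paired mode replicate counts must match within each
    sample and across sample/calibrator; with a single replicate the SD is
    0 with a warning.  Unpaired mode uses mean dCT per sample and
    propagates the dCT standard errors onto the fold-change scale.
    """
    if len(target_sample.cts) != len(ref_sample.cts):
        raise DomestiscanError("sample target/reference replicate counts differ")
    if len(target_calibrator.cts) != len(ref_calibrator.cts):
        raise DomestiscanError("calibrator target/reference replicate counts differ")

    dct_s = [t - r for t, r in zip(target_sample.cts, ref_sample.cts)]
    dct_c = [t - r for t, r in zip(target_calibrator.cts, ref_calibrator.cts)]

    if paired:
        if len(dct_s) != len(dct_c):
            raise DomestiscanError(
                "paired mode requires equal replicate counts in sample and calibrator"
            )
        rq = [2.0 ** -(s - c) for s, c in zip(dct_s, dct_c)]
        mean = statistics.fmean(rq)
        if len(rq) == 1:
            logger.warning("single replicate: fold-change SD reported as 0")
            sd = 0.0
        else:
            sd = statistics.stdev(rq)
        return mean, sd, rq

    ddct_mean = statistics.fmean(dct_s) - statistics.fmean(dct_c)
    mean = 2.0 ** -ddct_mean
    se2 = 0.0
    for d in (dct_s, dct_c):
        if len(d) > 1:
            se2 += statistics.variance(d) / len(d)
    sd = mean * math.log(2) * math.sqrt(se2)
    return mean, sd, [mean]


def read_ct_table(path) -> list[CtRecord]:
    """Read a CT TSV (sample, tissue, gene, rep1..repK) into records."""
    df = pd.read_csv(path, sep="\t")
    rep_cols = [c for c in df.columns if c.startswith("rep")]
    if not rep_cols:
        raise DomestiscanError("CT table has no rep* columns")
    return [
        CtRecord(
            sample=str(r["sample"]),
            tissue=str(r["tissue"]),
            gene=str(r["gene"]),
            cts=[float(r[c]) for c in rep_cols if pd.notna(r[c])],
        )
        for _, r in df.iterrows()
    ]


def relative_expression(
    records: list[CtRecord], calibrator_sample: str, paired: bool = True
) -> pd.DataFrame:
    """Per (sample, tissue) fold change relative to the calibrator sample.

    The calibrator's own tissue entries calibrate themselves (fold = 1 by
    identity when CTs are shared).
    """
    by_key: dict[tuple[str, str, str], CtRecord] = {
        (r.sample, r.tissue, r.gene): r for r in records
    }
    samples = sorted({r.sample for r in records})
    tissues = sorted({r.tissue for r in records})
    rows = []
    for tissue in tissues:
        cal_t = by_key.get((calibrator_sample, tissue, "target"))
        cal_r = by_key.get((calibrator_sample, tissue, "reference"))
        if cal_t is None or cal_r is None:
            logger.warning("no calibrator records for tissue %s; skipped", tissue)
            continue
        for sample in samples:
            st = by_key.get((sample, tissue, "target"))
            sr = by_key.get((sample, tissue, "reference"))
            if st is None or sr is None:
                continue
            mean, sd, _ = ddct(st, sr, cal_t, cal_r, paired=paired)
            rows.append(
                {"sample": sample, "tissue": tissue, "fold_change": mean, "sd": sd}
            )
    return pd.DataFrame(rows)
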