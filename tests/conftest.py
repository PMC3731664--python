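import pytest

from domestiscan import synth
from domestiscan.panel_io import AccessionMeta, Panel


@pytest.fixture(scope="session")
def paper_panel():
    """Preset panel: 21 wild / 158 cultivated, 13 planted variants."""
    panel, truth = synth.paper_like_panel(seed=1)
    return panel, truth


@pytest.fixture()
def tiny_panel():
    """Three accessions, one SNP column (col 5: A/A/T), anchor 13300."""
    seqs = {
        "W1": "ACGTAACGTA",
        "W2": "ACGTAACGTA",
        "C1": "ACGTATCGTA",
    }
    meta = [
        AccessionMeta("W1", "wild", "spread"),
        AccessionMeta("W2", "wild", "spread"),
        AccessionMeta("C1", "cultivated", "compact"),
    ]
    return Panel(sequences=seqs, meta=meta, anchor_upstream_bp=13300)


def make_panel(seqs_by_group, anchor=None):
    """Build a panel from {'wild': [...], 'cultivated': [...]} sequence lists."""
    sequences, meta = {}, []
    for group, pheno, prefix in (
        ("wild", "spread", "W"),
        ("cultivated", "compact", "C"),
    ):
        for k, seq in enumerate(seqs_by_group.get(group, [])):
            acc = f"{prefix}{k + 1}"
            sequences[acc] = seq
            meta.append(AccessionMeta(acc, group, pheno))
    length = len(next(iter(sequences.values())))
    return Panel(
        sequences=sequences,
        meta=meta,
        anchor_upstream_bp=anchor if anchor is not None else length + 10000,
    )
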