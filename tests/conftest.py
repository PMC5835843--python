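"""Shared fixtures: a hand-built mir16-like reference and seeded toy refs.

All fixtures are generated programmatically; nothing is read from disk
except what a test writes itself.
"""

from __future__ import annotations

import pytest

from isomirseq.preprocess import DEFAULT_ADAPTER, ReadRecord
from isomirseq.reference import build_reference
from isomirseq.simulate import _FILLER, make_toy_reference

# canonical mature miR-16-5p (22 nt), embedded in a synthetic hairpin with
# 5-nt flanks and an 8-nt loop; the 3p arm is an arbitrary distinct 22-mer
MIR16_5P = "TAGCAGCACGTAAATATTGGCG"
TOY_3P = "CCAGTATTAACTGTGCTGCTGA"
HP1 = "GGCAC" + MIR16_5P + "TTTGAGGT" + TOY_3P + "AGTAC"

GOOD_QUAL_50 = chr(33 + 38) * 50


@pytest.fixture(scope="session")
def mir16_ref():
    """One hairpin, both arms annotated, fully known coordinates."""
    return build_reference(
        {"hp1": HP1},
        [
            ("toy-miR-16-5p", "hp1", "5p", 5, 27),
            ("toy-miR-16-3p", "hp1", "3p", 35, 57),
        ],
    )


@pytest.fixture(scope="session")
def toy_ref():
    """Seeded 3-hairpin generated reference (6 matures, >=6 edits apart)."""
    return make_toy_reference(n_hairpins=3, seed=11)


def make_read(read_id: str, insert: str, read_length: int = 50,
              adapter: str = DEFAULT_ADAPTER, qual: str | None = None) -> ReadRecord:
    """Simulated raw read: insert + adapter + fixed filler, cut to length."""
    bases = (insert + adapter + _FILLER)[:read_length]
    quals = (qual or GOOD_QUAL_50)[: len(bases)]
    return ReadRecord(read_id, bases, quals)


@pytest.fixture()
def five_read_fastq():
    """The canonical 5-fate fixture: one read per preprocessing outcome."""
    low_qual = chr(33 + 38) * 40 + chr(33 + 2) * 10  # 20% of bases at Q2
    adapterless = ("ACGT" * 13)[:50]  # no adapter, no >=5-nt prefix at 3' end
    return [
        make_read("clean", MIR16_5P),
        make_read("adapter_only", ""),
        ReadRecord("no_adapter", adapterless, GOOD_QUAL_50),
        make_read("short_insert", MIR16_5P[:10]),
        make_read("low_quality", MIR16_5P, qual=low_qual),
    ]
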