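import numpy as np
import pytest

from symbiodiff.genome_io import Feature, GenomeRecord


@pytest.fixture
def tiny_record() -> GenomeRecord:
    """100 bp genome: one CDS [10,40), one tRNA [30,50), rest IGR.

    The CDS/tRNA overlap on [30,40) exercises partition precedence.
    """
    rng = np.random.default_rng(42)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 100)])
    # make the CDS a clean ORF: ATG + 8 stop-free codons + TAA
    cds = "ATG" + "AAA CCC GGG TTT AAC CCA GGT TTG".replace(" ", "") + "TAA"
    seq = seq[:10] + cds + seq[40:]
    return GenomeRecord(
        id="tiny", sequence=seq, circular=False,
        features=[
            Feature(kind="CDS", strand="+", intervals=[(10, 40)], name="cdsA",
                    qualifiers={"locus_tag": "cdsA"}),
            Feature(kind="tRNA", strand="+", intervals=[(30, 50)], name="trnX",
                    qualifiers={"anticodon": "CTT"}),
        ])


@pytest.fixture
def annotated_300bp() -> GenomeRecord:
    """Hand-built 300 bp record with 2 CDS (one minus-strand) and 1 pseudogene
    at known coordinates."""
    rng = np.random.default_rng(7)
    seq = list("".join(np.array(list("ACGT"))[rng.integers(0, 4, 300)]))
    plus = "ATGGCTGCAGCTTAA"                       # 15 bp ORF at [20, 35)
    seq[20:35] = plus
    # minus-strand ORF at [100, 115): genome holds revcomp(ORF)
    minus_orf = "ATGAAAGAACGTTGA"
    rc = minus_orf.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    seq[100:115] = rc
    return GenomeRecord(
        id="fix300", sequence="".join(seq), circular=True,
        features=[
            Feature(kind="CDS", strand="+", intervals=[(20, 35)], name="gA",
                    qualifiers={"locus_tag": "gA"}),
            Feature(kind="CDS", strand="-", intervals=[(100, 115)], name="gB",
                    qualifiers={"locus_tag": "gB"}),
            Feature(kind="pseudogene", strand="+", intervals=[(200, 260)],
                    name="psC", qualifiers={"original_key": "CDS"}),
        ])


def random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def mutate(rng: np.random.Generator, seq: str, n_sub: int, n_indel: int) -> str:
    """Random near-identical partner sequence for alignment tests."""
    s = list(seq)
    for _ in range(n_sub):
        i = int(rng.integers(0, len(s)))
        s[i] = "ACGT"[int(rng.integers(0, 4))]
    for _ in range(n_indel):
        i = int(rng.integers(1, len(s) - 2))
        if rng.random() < 0.5:
            ln = int(rng.integers(1, 4))
            del s[i:i + ln]
        else:
            ins = "".join("ACGT"[int(rng.integers(0, 4))]
                          for _ in range(int(rng.integers(1, 4))))
            s[i:i] = list(ins)
    return "".join(s)
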