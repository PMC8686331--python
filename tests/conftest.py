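import numpy as np
import pytest

from mutblot.sbs_io import MutationSequence, SBSRecord, write_maf
from mutblot.synthetic_data import _write_fasta


@pytest.fixture
def cattg_sequence():
    """The worked micro-example: CATTG with T>C at the middle position."""
    return MutationSequence("CA", "T", "C", "TG")


@pytest.fixture
def toy_genome(tmp_path):
    """A 40-base single-chromosome genome with known sequence."""
    from mutblot.sbs_io import GenomeSource

    seq = "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT"
    path = tmp_path / "toy.fa"
    _write_fasta(path, "chr1", seq)
    return GenomeSource(path), seq


@pytest.fixture
def toy_maf(tmp_path):
    """A small MAF with 2 valid SNPs, one deletion and one ref==alt row."""
    path = tmp_path / "toy.maf"
    lines = [
        "Hugo_Symbol\tChromosome\tStart_Position\tReference_Allele\t"
        "Tumor_Seq_Allele2\tTumor_Sample_Barcode",
        "TP53\tchr1\t5\tA\tT\tTCGA-AA-0001-01",
        "TTN\tchr1\t10\tC\tG\tTCGA-AA-0002-01",
        "KRAS\tchr1\t15\tAT\t-\tTCGA-AA-0001-01",
        "EGFR\tchr1\t20\tC\tC\tTCGA-AA-0002-01",
    ]
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def random_encodings():
    """Stack of 30 random valid encodings with F=5 (site index 5)."""
    rng = np.random.default_rng(42)
    bases = np.array([(0, 0), (0, 1), (1, 0), (1, 1)], dtype=float)
    B, F = 30, 5
    n = 2 * F + 1
    enc = np.empty((B, n, 4))
    for b in range(B):
        idx = rng.integers(0, 4, size=n)
        enc[b, :, :2] = bases[idx]
        enc[b, :, 2:] = bases[idx]
        ref, alt = rng.choice(4, size=2, replace=False)
        enc[b, F, :2] = bases[alt]
        enc[b, F, 2:] = bases[ref]
    return enc
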