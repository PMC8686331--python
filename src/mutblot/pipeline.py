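"""Convenience glue: MAF + genome -> encoded dataset ready for training."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .encoding import encode_batch
from .sbs_io import GenomeSource, extract_all_flanks, read_maf


def load_encoded_dataset(
    maf_path: str | Path,
    genome: GenomeSource | str | Path,
    F: int = 50,
    on_mismatch: str = "raise",
):
    """Read a MAF, pull flanks from the genome and encode everything.

    Returns (records, sequences, encodings) where ``encodings`` is the
    float (N, 2F+1, 4) stack fed to the trainer.
    """
    if not isinstance(genome, GenomeSource):
        genome = GenomeSource(genome)
    records = read_maf(maf_path)
    sequences = extract_all_flanks(records, genome, F=F, on_mismatch=on_mismatch)
    kept_records = [s.record for s in sequences]
    encodings = encode_batch(sequences)
    return kept_records, sequences, encodings
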