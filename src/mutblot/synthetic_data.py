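"""Synthetic cohorts with planted flank-context classes.

The generator emulates the three real inputs of the pipeline — a
reference genome (FASTA), somatic SBS calls (MAF) and a clinical table —
with a hidden class planted in every SBS.  Each class has a
ContextProfile: a distribution over the six canonical substitution types
and position-dependent base probabilities for the flanks that decay
toward the uniform composition with distance from the mutation site
(mirroring how real flank composition balances out away from the site).
Planted flanks are written into a scratch copy of the reference so that
ordinary flank extraction reproduces the planted context exactly.

Patient survival is exponential with an archetype-dependent hazard and
independent uniform censoring; clinical covariates (age, sex, weight,
stages) are drawn independently of the archetype unless shifted
explicitly.  The hidden truth (per-SBS class, per-patient archetype) is
written to separate files that the clustering path never sees.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .encoding import CANONICAL_TYPES
from .sbs_io import GenomeSource, SBSRecord, write_maf

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass
class ContextProfile:
    """Planted sequence-context signature of one hidden class.

    ``base_probs`` has one row per flank position, ordered -F..-1 then
    +1..+F, with columns A/C/G/T; every row sums to 1.
    """

    class_id: int
    sub_probs: dict[str, float]
    base_probs: np.ndarray

    def __post_init__(self) -> None:
        self.base_probs = np.asarray(self.base_probs, dtype=np.float64)
        total = sum(self.sub_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"substitution probabilities sum to {total}, not 1")
        if unknown := set(self.sub_probs) - set(CANONICAL_TYPES):
            raise ValueError(f"non-canonical substitution types: {unknown}")
        if not np.allclose(self.base_probs.sum(axis=1), 1.0):
            raise ValueError("each base-probability row must sum to 1")

    @property
    def flank_length(self) -> int:
        return self.base_probs.shape[0] // 2


@dataclass
class Archetype:
    """A patient archetype: class mixture plus survival hazard (per day)."""

    name: str
    mixture: np.ndarray
    hazard: float
    age_shift: float = 0.0

    def __post_init__(self) -> None:
        self.mixture = np.asarray(self.mixture, dtype=np.float64)
        if abs(self.mixture.sum() - 1.0) > 1e-9:
            raise ValueError("mixture must sum to 1")
        if self.hazard <= 0:
            raise ValueError("hazard must be > 0")


@dataclass
class SyntheticSpec:
    n_patients: int
    archetypes: list[Archetype]
    sbs_per_patient: int = 50
    poisson_counts: bool = False
    flank_length: int = 10
    censor_horizon: float = 2000.0
    genes: Sequence[str] = ("TTN", "TP53", "MUC16", "PIK3CA", "BRAF")
    mean_age: float = 63.0
    sd_age: float = 11.0
    mean_weight: float = 76.0
    sd_weight: float = 14.0


def flank_positions(F: int) -> np.ndarray:
    """Signed flank positions in profile row order: -F..-1, +1..+F."""
    return np.concatenate([np.arange(-F, 0), np.arange(1, F + 1)])


def make_profile(
    class_id: int,
    sub_type: str,
    dominant_base: str,
    F: int,
    dominant_prob: float = 0.9,
    decay_scale: float = 8.0,
) -> ContextProfile:
    """Single-type profile whose flanks are enriched for one base.

    The enrichment is ``dominant_prob`` at the positions adjacent to the
    site and decays exponentially toward the uniform 0.25 with distance.
    """
    dist = np.abs(flank_positions(F)).astype(float)
    p_dom = 0.25 + (dominant_prob - 0.25) * np.exp(-(dist - 1.0) / decay_scale)
    base_probs = np.tile((1.0 - p_dom)[:, None] / 3.0, (1, 4))
    base_probs[:, _BASE_INDEX[dominant_base]] = p_dom
    return ContextProfile(
        class_id=class_id, sub_probs={sub_type: 1.0}, base_probs=base_probs
    )


def make_profiles(n_classes: int, F: int, **kwargs) -> list[ContextProfile]:
    """Deterministic bank of well-separated profiles.

    Classes cycle through the 6 canonical types and 4 dominant flank
    bases so every (type, base) pair is distinct for n_classes <= 24.
    """
    if n_classes > 24:
        raise ValueError("at most 24 distinct (type, base) profiles available")
    profiles = []
    for k in range(n_classes):
        sub = CANONICAL_TYPES[k % 6]
        base = "TAGC"[(k // 6 + k) % 4]
        profiles.append(make_profile(k, sub, base, F, **kwargs))
    return profiles


def profile_separation(a: ContextProfile, b: ContextProfile) -> float:
    """Separation between two profiles: max total-variation distance over
    the substitution distribution and the near-site flank positions."""
    pa = np.array([a.sub_probs.get(t, 0.0) for t in CANONICAL_TYPES])
    pb = np.array([b.sub_probs.get(t, 0.0) for t in CANONICAL_TYPES])
    tv_sub = 0.5 * np.abs(pa - pb).sum()
    tv_flank = 0.5 * np.abs(a.base_probs - b.base_probs).sum(axis=1).max()
    return float(max(tv_sub, tv_flank))


def generate_reference(
    length: int,
    gc: float,
    seed: int,
    path: str | Path,
    flank_length: int = 50,
    chromosome: str = "chr1",
) -> GenomeSource:
    """Write an i.i.d. random single-chromosome FASTA and open it indexed."""
    if not 0 < gc < 1:
        raise ValueError(f"gc must be strictly inside (0, 1), got {gc}")
    if length < 2 * flank_length + 1:
        raise ValueError(
            f"genome length {length} is shorter than one flanked site "
            f"(2F+1 = {2 * flank_length + 1})"
        )
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = "".join(np.array(list(BASES))[rng.choice(4, size=length, p=p)])
    _write_fasta(path, chromosome, seq)
    return GenomeSource(path)


def _write_fasta(path: str | Path, name: str, seq: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i:i + width] + "\n")
    # refresh any stale index
    fai = Path(str(path) + ".fai")
    if fai.exists():
        fai.unlink()


def generate_cohort(
    spec: SyntheticSpec,
    profiles: Sequence[ContextProfile],
    genome: GenomeSource,
    outdir: str | Path,
    seed: int = 0,
    min_separation: float = 0.2,
) -> dict[str, Path]:
    """Generate a planted cohort; returns paths of the files written.

    Files: ``reference_planted.fa`` (genome copy with planted flanks),
    ``cohort.maf``, ``clinical.csv``, ``truth_sbs.tsv`` and
    ``truth_patients.tsv`` (hidden labels, kept out of the MAF/clinical
    schemas so the clustering path cannot see them).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    F = spec.flank_length
    for p in profiles:
        if p.flank_length != F:
            raise ValueError("profile flank length does not match spec")
    for i in range(len(profiles)):
        for j in range(i + 1, len(profiles)):
            sep = profile_separation(profiles[i], profiles[j])
            if sep < min_separation:
                raise ValueError(
                    f"profiles {i} and {j} are too similar "
                    f"(separation {sep:.3f} < {min_separation})"
                )
    for arch in spec.archetypes:
        if arch.mixture.size != len(profiles):
            raise ValueError("archetype mixture length != number of profiles")

    rng = np.random.default_rng(seed)
    chrom = genome.chromosomes()[0]
    chrom_seq = list(genome.fetch(chrom, 0, genome.chromosome_length(chrom)))

    # per-patient archetypes and SBS counts
    arch_idx = rng.integers(0, len(spec.archetypes), size=spec.n_patients)
    if spec.poisson_counts:
        counts = np.maximum(1, rng.poisson(spec.sbs_per_patient, size=spec.n_patients))
    else:
        counts = np.full(spec.n_patients, spec.sbs_per_patient)
    n_total = int(counts.sum())

    spacing = 2 * F + 2
    first = F + 1  # 1-based position of the first site
    needed = first + (n_total - 1) * spacing + F
    if needed > len(chrom_seq):
        raise ValueError(
            f"genome too short: need {needed} bases for {n_total} sites, "
            f"have {len(chrom_seq)}"
        )
    positions = first + spacing * rng.permutation(n_total)

    records: list[SBSRecord] = []
    truth_rows = []
    site_cursor = 0
    genes = list(spec.genes)
    for pi in range(spec.n_patients):
        barcode = f"SYN-{pi:04d}-01"
        arch = spec.archetypes[arch_idx[pi]]
        classes = rng.choice(len(profiles), size=counts[pi], p=arch.mixture)
        for cls in classes:
            prof = profiles[cls]
            pos = int(positions[site_cursor])
            site_cursor += 1
            subs = list(prof.sub_probs)
            sub = subs[rng.choice(len(subs), p=[prof.sub_probs[s] for s in subs])]
            ref, alt = sub[0], sub[2]
            # plant flanks and reference base into the scratch genome copy
            flank = [
                BASES[k]
                for k in (
                    rng.random((2 * F, 1)) > prof.base_probs.cumsum(axis=1)[:, :-1]
                ).sum(axis=1)
            ]
            chrom_seq[pos - 1 - F: pos - 1] = flank[:F]
            chrom_seq[pos - 1] = ref
            chrom_seq[pos: pos + F] = flank[F:]
            gene = genes[rng.integers(len(genes))]
            records.append(
                SBSRecord(
                    sample_barcode=barcode,
                    chromosome=chrom,
                    position=pos,
                    ref_allele=ref,
                    alt_allele=alt,
                    gene_symbol=gene,
                    cancer_type=arch.name,
                )
            )
            truth_rows.append((barcode, chrom, pos, int(cls)))

    # clinical table with archetype-dependent survival
    clinical_lines = [
        "sample_barcode,age,sex,weight,t_stage,n_stage,m_stage,ajcc_stage,"
        "survival_time,event"
    ]
    patient_truth = ["sample_barcode\tarchetype"]
    for pi in range(spec.n_patients):
        barcode = f"SYN-{pi:04d}-01"
        arch = spec.archetypes[arch_idx[pi]]
        age = rng.normal(spec.mean_age + arch.age_shift, spec.sd_age)
        sex = "male" if rng.random() < 0.5 else "female"
        weight = rng.normal(spec.mean_weight, spec.sd_weight)
        t_stage = f"T{rng.integers(1, 5)}"
        n_stage = f"N{rng.integers(0, 4)}"
        m_stage = f"M{rng.integers(0, 2)}"
        ajcc = f"Stage {'I' * rng.integers(1, 5)}"
        death = rng.exponential(1.0 / arch.hazard)
        censor = rng.uniform(0, spec.censor_horizon)
        time = min(death, censor)
        event = int(death <= censor)
        clinical_lines.append(
            f"{barcode},{age:.1f},{sex},{weight:.1f},{t_stage},{n_stage},"
            f"{m_stage},{ajcc},{time:.1f},{event}"
        )
        patient_truth.append(f"{barcode}\t{arch.name}")

    ref_path = outdir / "reference_planted.fa"
    _write_fasta(ref_path, chrom, "".join(chrom_seq))
    maf_path = outdir / "cohort.maf"
    write_maf(records, maf_path)
    clinical_path = outdir / "clinical.csv"
    clinical_path.write_text("\n".join(clinical_lines) + "\n")
    truth_path = outdir / "truth_sbs.tsv"
    truth_path.write_text(
        "sample_barcode\tchromosome\tposition\thidden_class\n"
        + "\n".join("\t".join(map(str, row)) for row in truth_rows)
        + "\n"
    )
    patient_truth_path = outdir / "truth_patients.tsv"
    patient_truth_path.write_text("\n".join(patient_truth) + "\n")
    return {
        "reference": ref_path,
        "maf": maf_path,
        "clinical": clinical_path,
        "truth_sbs": truth_path,
        "truth_patients": patient_truth_path,
    }


def two_class_profiles(F: int = 10) -> list[ContextProfile]:
    """The two-class recovery benchmark: both classes are C>A, class 0
    with T-rich near flanks and class 1 with A-rich near flanks."""
    return [
        make_profile(0, "C>A", "T", F),
        make_profile(1, "C>A", "A", F),
    ]


def two_class_spec(n_patients: int = 40, sbs_per_patient: int = 50,
                   F: int = 10) -> SyntheticSpec:
    return SyntheticSpec(
        n_patients=n_patients,
        sbs_per_patient=sbs_per_patient,
        flank_length=F,
        archetypes=[
            Archetype("pure-0", [1.0, 0.0], hazard=1 / 800),
            Archetype("pure-1", [0.0, 1.0], hazard=1 / 800),
        ],
    )


def ten_class_spec(n_patients: int = 50, sbs_per_patient: int = 50,
                   F: int = 10) -> SyntheticSpec:
    eye = np.eye(10)
    return SyntheticSpec(
        n_patients=n_patients,
        sbs_per_patient=sbs_per_patient,
        flank_length=F,
        archetypes=[
            Archetype(f"pure-{k}", eye[k], hazard=1 / 800) for k in range(10)
        ],
    )


def survival_demo_spec(n_patients: int = 150, F: int = 10) -> SyntheticSpec:
    """Three composition archetypes with distinct hazards for the
    downstream clustering/survival demonstrations."""
    mixtures = np.array(
        [
            [0.70, 0.15, 0.15],
            [0.15, 0.70, 0.15],
            [0.15, 0.15, 0.70],
        ]
    )
    hazards = [1 / 1500, 1 / 600, 1 / 250]
    return SyntheticSpec(
        n_patients=n_patients,
        sbs_per_patient=60,
        flank_length=F,
        censor_horizon=2500.0,
        archetypes=[
            Archetype(f"arch-{k}", mixtures[k], hazard=hazards[k])
            for k in range(3)
        ],
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_fixtures(outdir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Emit the canned benchmark datasets used throughout the tests.

    (i) the CATTG>CACTG micro-example (1-row MAF + 5-base reference),
    (ii) a 2-class recovery set (n=2000 SBSs, F=10),
    (iii) a 10-class schedule set (n=2500, F=10),
    (iv) a 3-archetype survival demo cohort.
    A ``checksums.txt`` records the SHA-256 of every file written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    micro_dir = outdir / "micro"
    micro_dir.mkdir(exist_ok=True)
    micro_fa = micro_dir / "micro.fa"
    _write_fasta(micro_fa, "chr1", "CATTG")
    micro_maf = micro_dir / "micro.maf"
    write_maf(
        [SBSRecord("SYN-0000-01", "chr1", 3, "T", "C", gene_symbol="DEMO")],
        micro_maf,
    )
    paths["micro_fa"] = micro_fa
    paths["micro_maf"] = micro_maf

    rng_seeds = np.random.SeedSequence(seed).generate_state(4) % (2 ** 31)

    two_dir = outdir / "two_class"
    two_dir.mkdir(exist_ok=True)
    genome = generate_reference(
        60_000, gc=0.41, seed=int(rng_seeds[0]), path=two_dir / "base.fa",
        flank_length=10,
    )
    for k, v in generate_cohort(
        two_class_spec(), two_class_profiles(), genome, two_dir,
        seed=int(rng_seeds[0]),
    ).items():
        paths[f"two_class_{k}"] = v

    ten_dir = outdir / "ten_class"
    ten_dir.mkdir(exist_ok=True)
    genome = generate_reference(
        80_000, gc=0.41, seed=int(rng_seeds[1]), path=ten_dir / "base.fa",
        flank_length=10,
    )
    for k, v in generate_cohort(
        ten_class_spec(), make_profiles(10, F=10), genome, ten_dir,
        seed=int(rng_seeds[1]),
    ).items():
        paths[f"ten_class_{k}"] = v

    surv_dir = outdir / "survival"
    surv_dir.mkdir(exist_ok=True)
    genome = generate_reference(
        250_000, gc=0.41, seed=int(rng_seeds[2]), path=surv_dir / "base.fa",
        flank_length=10,
    )
    for k, v in generate_cohort(
        survival_demo_spec(), make_profiles(3, F=10), genome, surv_dir,
        seed=int(rng_seeds[2]),
    ).items():
        paths[f"survival_{k}"] = v

    checksums = outdir / "checksums.txt"
    lines = [
        f"{_sha256(p)}  {p.relative_to(outdir)}"
        for p in sorted(paths.values(), key=lambda p: str(p))
    ]
    checksums.write_text("\n".join(lines) + "\n")
    paths["checksums"] = checksums
    return paths
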