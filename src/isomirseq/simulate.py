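"""Synthetic small-RNA cohorts: reference, NB counts, isomiR-structured reads.

The generator emulates the statistical structure the analysis assumes for a
two-group tumor cohort: negative-binomial counts (variance mu + phi*mu^2)
over a configurable number of miRNA loci, one dominant locus holding a large
share of all counts, a fraction of loci with strong injected fold-changes,
and per-locus isomiR structure (3' trims, templated 3' extensions,
non-templated 3' tails, 5' shifts realized as insertion/deletion of "C",
internal substitutions), plus uniform sequencing error and a contaminant
read fraction drawn from a decoy set.

Three constructions keep the true read decomposition identifiable, so that a
zero-error simulation closes exactly under the aligner's minimal-score rule:
the two hairpin bases 5' of every mature are fixed to the 5'-shift indel base
(making shift reads templated), the first base of a non-templated tail always
differs from the hairpin's templated continuation, and internal substitutions
are placed at least max_tail+1 nt from the 3' end (otherwise a tail
decomposition with fewer substitutions would win).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .reference import HairpinRecord, MatureAnnotation, ReferenceSet

BASES = "ACGT"

ISOMIR_CLASSES = ("canonical", "trim3", "ext3", "nta3", "shift5", "subst")

#: default per-read isomiR class probabilities; 3'-end classes dominate and
#: roughly a third of variant reads carry or accompany nucleotide changes,
#: mirroring the qualitative composition reported for tumor small-RNA data.
DEFAULT_ISOMIR_PROFILE = {
    "canonical": 0.25,
    "trim3": 0.30,
    "ext3": 0.15,
    "nta3": 0.10,
    "shift5": 0.05,
    "subst": 0.15,
}


@dataclass
class SimulationConfig:
    """Cohort-level knobs; defaults are the study-like conditions.

    The discovery cohort compared 2 low-grade vs 7 high-grade samples, so the
    group sizes default to 2 and 7. ``abundance_skew`` is the count share of
    the dominant locus (the study's top miRNA held 18-48% per group).
    Injected effects exceed |log2FC| = 2, the strong-modulation threshold.
    """

    n_group_a: int = 2
    n_group_b: int = 7
    n_mirnas: int = 200
    library_size_mean: int = 1_000_000
    library_size_cv: float = 0.3
    dispersion: float = 0.2  # phi in var = mu + phi mu^2
    abundance_skew: float = 0.25
    de_fraction: float = 0.15
    de_log2fc_range: tuple[float, float] = (2.5, 4.5)
    isomir_profile: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ISOMIR_PROFILE)
    )
    shift5_indel_base: str = "C"
    seq_error_rate: float = 0.001
    contaminant_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_group_a < 2 or self.n_group_b < 2:
            raise ValueError("need at least 2 samples per group")
        if abs(sum(self.isomir_profile.values()) - 1.0) > 1e-9:
            raise ValueError("isomir_profile probabilities must sum to 1")
        if set(self.isomir_profile) - set(ISOMIR_CLASSES):
            raise ValueError(f"unknown isomiR classes: {set(self.isomir_profile) - set(ISOMIR_CLASSES)}")
        for name in ("abundance_skew", "de_fraction", "seq_error_rate", "contaminant_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 <= self.abundance_skew <= 0.6:
            raise ValueError("abundance_skew outside [0, 0.6]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.de_fraction > 0 and self.de_log2fc_range[0] <= 2:
            raise ValueError("de_log2fc_range low bound must exceed 2")


@dataclass
class GroundTruth:
    """Everything the simulator decided, for closure and recovery tests."""

    abundances: pd.Series  # per-locus baseline relative abundance
    log2fc: pd.Series  # injected effect (0 for null loci)
    library_sizes: pd.Series
    groups: pd.Series  # sample -> {A, B}
    counts: pd.DataFrame  # loci x samples
    provenance: pd.DataFrame | None = None  # one row per emitted read


def _sample_names(cfg: SimulationConfig) -> tuple[list[str], list[str]]:
    a = [f"A{i + 1}" for i in range(cfg.n_group_a)]
    b = [f"B{i + 1}" for i in range(cfg.n_group_b)]
    return a, b


def simulate_reference(
    n_mirnas: int, seed: int, upstream_base: str = "C"
) -> ReferenceSet:
    """Random hairpins (60-90 nt) carrying one 20-23 nt mature arm.

    Matures sit >= 10 nt from both hairpin ends, leaving template for end
    shifts and extensions; the two bases immediately 5' of the mature are set
    to ``upstream_base`` so simulated 5'-shift insertions are templated.
    """
    if n_mirnas < 1:
        raise ValueError("n_mirnas must be >= 1")
    rng = np.random.default_rng(seed)
    ref = ReferenceSet()
    width = max(3, len(str(n_mirnas)))
    for i in range(n_mirnas):
        hp_len = int(rng.integers(60, 91))
        seq = list(rng.choice(list(BASES), size=hp_len))
        m_len = int(rng.integers(20, 24))
        start = int(rng.integers(10, hp_len - m_len - 10 + 1))
        seq[start - 2] = upstream_base
        seq[start - 1] = upstream_base
        hp_id = f"sim-mir-{i + 1:0{width}d}"
        arm = "5p" if start + m_len / 2 < hp_len / 2 else "3p"
        mature_id = f"sim-miR-{i + 1:0{width}d}-{arm}"
        hairpin = HairpinRecord(hp_id, "".join(seq))
        ref.add(hairpin, [MatureAnnotation(mature_id, hp_id, start, start + m_len, arm)])
    return ref


def simulate_counts(cfg: SimulationConfig, ref: ReferenceSet) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw the loci x samples NB count matrix and its ground truth.

    Baseline relative abundances give ``abundance_skew`` to the first locus
    and distribute the rest log-normally (sigma = 1); group-B means of the DE
    loci are scaled by 2**log2fc, with balanced up/down signs.
    """
    rng = np.random.default_rng(cfg.seed)
    loci = ref.mature_ids()
    n = len(loci)
    if n == 1:
        abund = np.array([1.0])
    else:
        rest = rng.lognormal(mean=0.0, sigma=1.0, size=n - 1)
        rest = rest / rest.sum() * (1.0 - cfg.abundance_skew)
        abund = np.concatenate([[cfg.abundance_skew], rest])
        if cfg.abundance_skew == 0:
            abund = rng.lognormal(mean=0.0, sigma=1.0, size=n)
            abund /= abund.sum()

    lfc = np.zeros(n)
    n_de = int(round(cfg.de_fraction * n))
    if n_de:
        # the dominant locus stays null (the most abundant miRNA in tumor
        # cohorts is typically stable across groups), and up/down signs are
        # assigned to balance the count-mass shift, so library totals and
        # hence CPM fold-changes stay anchored under the injected effects
        eligible = np.arange(1, n) if cfg.abundance_skew > 0 and n > 1 else np.arange(n)
        n_de = min(n_de, len(eligible))
        de_idx = rng.choice(eligible, size=n_de, replace=False)
        mags = rng.uniform(*cfg.de_log2fc_range, size=n_de)
        order = np.argsort(-abund[de_idx])
        shift = 0.0
        for k in order:
            i, m = de_idx[k], mags[k]
            up = abund[i] * (2.0**m - 1.0)
            down = abund[i] * (2.0**-m - 1.0)
            if abs(shift + up) <= abs(shift + down):
                lfc[i], shift = m, shift + up
            else:
                lfc[i], shift = -m, shift + down

    a_names, b_names = _sample_names(cfg)
    samples = a_names + b_names
    sigma2 = np.log1p(cfg.library_size_cv**2)
    libs = rng.lognormal(
        mean=np.log(cfg.library_size_mean) - sigma2 / 2,
        sigma=np.sqrt(sigma2),
        size=len(samples),
    )
    counts = np.zeros((n, len(samples)), dtype=np.int64)
    for j, s in enumerate(samples):
        eff = 2.0**lfc if s in b_names else np.ones(n)
        mu = libs[j] * abund * eff
        if cfg.dispersion == 0:
            counts[:, j] = rng.poisson(mu)
        else:
            r = 1.0 / cfg.dispersion
            counts[:, j] = rng.negative_binomial(r, r / (r + mu))
    frame = pd.DataFrame(counts, index=pd.Index(loci, name="feature"), columns=samples)
    truth = GroundTruth(
        abundances=pd.Series(abund, index=loci),
        log2fc=pd.Series(lfc, index=loci),
        library_sizes=pd.Series(libs, index=samples),
        groups=pd.Series(["A"] * len(a_names) + ["B"] * len(b_names), index=samples),
        counts=frame,
    )
    return frame, truth


def simulate_nb_matrix(
    n_features: int,
    n_a: int,
    n_b: int,
    dispersion: float,
    seed: int,
    mean_range: tuple[float, float] = (20.0, 500.0),
    log2fc: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Plain NB matrix with log-uniform feature means; no read structure.

    Convenience for calibration studies (type-I error, dispersion recovery)
    where the full cohort generator's abundance skew is not wanted.
    """
    rng = np.random.default_rng(seed)
    mu = np.exp(rng.uniform(np.log(mean_range[0]), np.log(mean_range[1]), size=n_features))
    lfc = np.zeros(n_features) if log2fc is None else np.asarray(log2fc, dtype=float)
    samples = [f"A{i+1}" for i in range(n_a)] + [f"B{i+1}" for i in range(n_b)]
    groups = pd.Series(["A"] * n_a + ["B"] * n_b, index=samples)
    counts = np.zeros((n_features, n_a + n_b), dtype=np.int64)
    for j in range(n_a + n_b):
        m = mu * (2.0**lfc if j >= n_a else 1.0)
        if dispersion == 0:
            counts[:, j] = rng.poisson(m)
        else:
            r = 1.0 / dispersion
            counts[:, j] = rng.negative_binomial(r, r / (r + m))
    idx = pd.Index([f"f{i+1}" for i in range(n_features)], name="feature")
    return pd.DataFrame(counts, index=idx, columns=samples), groups


def simulate_decoys(n_decoys: int = 20, seed: int = 0) -> list[tuple[str, str]]:
    """Random rRNA/tRNA-fragment-like decoy sequences (id, sequence)."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_decoys):
        length = int(rng.integers(80, 301))
        seq = "".join(rng.choice(list(BASES), size=length))
        out.append((f"decoy-{i + 1:03d}", seq))
    return out


def write_decoy_fasta(decoys: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in decoys:
            fh.write(f">{name}\n{seq}\n")


# ---------------------------------------------------------------------------
# read emission

MAX_TAIL_GUARD = 3  # keep substitutions > this many nt from the 3' end


def _make_read(
    rng: np.random.Generator, cls: str, ref: ReferenceSet, mature_id: str, cfg: SimulationConfig
) -> tuple[str, int, int, str, str]:
    """Construct one error-free read: (seq, offset5, offset3, tail, subst)."""
    m = ref.mature(mature_id)
    hp = ref.hairpins[m.hairpin_id].sequence
    mature = hp[m.start : m.end]
    if cls == "canonical":
        return mature, 0, 0, "", ""
    if cls == "trim3":
        k = int(rng.integers(1, 4))
        return mature[:-k], 0, -k, "", ""
    if cls == "ext3":
        k = int(rng.integers(1, 4))
        return hp[m.start : m.end + k], 0, k, "", ""
    if cls == "nta3":
        k = int(rng.integers(1, 4))
        nxt = hp[m.end] if m.end < len(hp) else ""
        first_choices = [b for b in "AT" if b != nxt]
        tail = rng.choice(first_choices) + "".join(rng.choice(list("AT"), size=k - 1))
        return mature + tail, 0, 0, tail, ""
    if cls == "shift5":
        delta = int(rng.choice([-2, -1, 1, 2]))
        return hp[m.start + delta : m.end], delta, 0, "", ""
    if cls == "subst":
        L = len(mature)
        pos = int(rng.integers(1, L - MAX_TAIL_GUARD))  # in [1, L-1-max_tail]
        old = mature[pos]
        new = rng.choice([b for b in BASES if b != old])
        seq = mature[:pos] + new + mature[pos + 1 :]
        return seq, 0, 0, "", f"{pos}:{old}>{new}"
    raise ValueError(f"unknown isomiR class {cls!r}")


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> tuple[str, int]:
    if rate <= 0:
        return seq, 0
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    if hits.size == 0:
        return seq, 0
    out = list(seq)
    for i in hits:
        out[i] = rng.choice([b for b in BASES if b != out[i]])
    return "".join(out), int(hits.size)


def emit_reads(
    counts: pd.DataFrame,
    truth: GroundTruth,
    ref: ReferenceSet,
    cfg: SimulationConfig,
    outdir: str | Path,
    decoys: list[tuple[str, str]] | None = None,
    gzip_fastq: bool = True,
) -> dict[str, Path]:
    """Expand each count unit into one FASTQ read with known provenance.

    Writes one FASTQ per sample plus ``truth_reads.tsv`` and the decoy FASTA;
    qualities are constant 'I'. Returns sample -> FASTQ path; the provenance
    table is attached to ``truth.provenance``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed + 1)
    if decoys is None:
        decoys = simulate_decoys(seed=cfg.seed + 2)
    write_decoy_fasta(decoys, outdir / "decoys.fasta")

    classes = list(cfg.isomir_profile)
    probs = np.array([cfg.isomir_profile[c] for c in classes])
    paths: dict[str, Path] = {}
    prov_rows = []
    for sample in counts.columns:
        suffix = ".fastq.gz" if gzip_fastq else ".fastq"
        path = outdir / f"{sample}{suffix}"
        opener = gzip.open if gzip_fastq else open
        serial = 0
        with opener(path, "wt") as fh:
            for mature_id, c in counts[sample].items():
                if c == 0:
                    continue
                class_counts = rng.multinomial(int(c), probs)
                for cls, k in zip(classes, class_counts):
                    for _ in range(int(k)):
                        seq, o5, o3, tail, subst = _make_read(rng, cls, ref, mature_id, cfg)
                        seq, n_err = _apply_errors(rng, seq, cfg.seq_error_rate)
                        serial += 1
                        rid = f"sim_{sample}_{serial}"
                        fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
                        prov_rows.append(
                            (rid, sample, mature_id, cls, o5, o3, tail, subst, n_err)
                        )
            n_mirna = int(counts[sample].sum())
            n_cont = int(round(cfg.contaminant_fraction / (1 - cfg.contaminant_fraction) * n_mirna)) if cfg.contaminant_fraction > 0 else 0
            for _ in range(n_cont):
                name, dseq = decoys[int(rng.integers(len(decoys)))]
                L = int(rng.integers(18, 36))
                start = int(rng.integers(0, len(dseq) - L + 1))
                seq = dseq[start : start + L]
                serial += 1
                rid = f"sim_{sample}_{serial}"
                fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
                prov_rows.append((rid, sample, "contaminant", "contaminant", 0, 0, "", "", 0))
        paths[sample] = path

    truth.provenance = pd.DataFrame(
        prov_rows,
        columns=["read_id", "sample", "locus", "iso_class", "offset5", "offset3",
                 "tail", "substitutions", "n_errors"],
    )
    truth.provenance.to_csv(outdir / "truth_reads.tsv", sep="\t", index=False)
    return paths
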