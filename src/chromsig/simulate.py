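"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of its seed and returns ground truth
alongside the data, so parameter-recovery tests can score every
downstream stage: overlapping per-sample peak calls with
group-structured occupancy, negative-binomial fragment counts with
planted group-differential regions, short expression time courses with
planted up/flat/down temporal classes, and expression + survival
cohorts where a planted gene subset drives the hazard of an
exponential-baseline Cox model under calibrated independent censoring.

Defaults mirror the study design the pipeline was built around: a
5-vs-3 two-group chromatin comparison, a 6-point hormone-stimulation
time course, and a 131-patient primary-tumor cohort with roughly 75%
censoring of biochemical recurrence.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .diffbind import CountMatrix, GroupDesign
from .intervals import GeneModel, GenomicInterval, GenomeLayout, PeakSet
from .survival import CohortData
from .temporal import TimeCourse

__all__ = [
    "PeakLandscapeTruth",
    "CountTruth",
    "TimecourseTruth",
    "CohortTruth",
    "simulate_peak_landscape",
    "simulate_counts",
    "simulate_timecourse",
    "simulate_cohort",
    "simulate_discovery_bundle",
]


def _truth_to_json(truth, path) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(truth), fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


# ---------------------------------------------------------------------------
# Peak landscapes


@dataclass
class PeakLandscapeTruth:
    shared_regions: list[tuple[str, int, int]]
    group_a_regions: list[tuple[str, int, int]]
    group_b_regions: list[tuple[str, int, int]]
    samples_a: list[str]
    samples_b: list[str]
    seed: int

    def to_json(self, path) -> None:
        _truth_to_json(self, path)


def simulate_peak_landscape(
    n_samples: tuple[int, int] = (5, 3),
    n_shared: int = 300,
    n_group_specific: int = 40,
    genome: GenomeLayout | None = None,
    peak_width: int = 400,
    jitter_bp: int = 50,
    gene_fraction: float = 0.5,
    seed: int = 0,
) -> tuple[dict[str, PeakSet], list[GeneModel], PeakLandscapeTruth]:
    """Per-sample peak calls with shared and group-specific regions.

    Shared peaks appear (with +/- jitter) in every sample of both
    groups; group-specific peaks only within their group. Peak slots
    are laid out with enough spacing that jittered calls of different
    slots never merge. Toy gene models are emitted so roughly
    ``gene_fraction`` of slots fall in promoters or gene bodies, the
    rest in distal space.
    """
    genome = genome or GenomeLayout({"chr1": 40_000_000, "chr2": 30_000_000})
    rng = np.random.default_rng(seed)
    n_a, n_b = n_samples
    total_slots = n_shared + 2 * n_group_specific
    spacing = peak_width + 4 * jitter_bp + peak_width  # no cross-slot merge
    chroms = sorted(genome.chrom_sizes)
    capacity = sum(
        (genome.chrom_sizes[c] - spacing) // spacing for c in chroms
    )
    if capacity < total_slots:
        raise ValueError(
            f"genome too small: {total_slots} slots requested, {capacity} fit"
        )
    # deterministic slot layout round-robin over chromosomes
    slots: list[tuple[str, int]] = []
    per_chrom = {c: spacing for c in chroms}
    ci = 0
    while len(slots) < total_slots:
        c = chroms[ci % len(chroms)]
        pos = per_chrom[c]
        if pos + spacing < genome.chrom_sizes[c]:
            slots.append((c, pos))
            per_chrom[c] = pos + spacing
        ci += 1
    shared = slots[:n_shared]
    group_a = slots[n_shared : n_shared + n_group_specific]
    group_b = slots[n_shared + n_group_specific :]

    samples_a = [f"A{i + 1}" for i in range(n_a)]
    samples_b = [f"B{i + 1}" for i in range(n_b)]
    peaksets: dict[str, PeakSet] = {}
    for s in samples_a + samples_b:
        own = list(shared)
        if s in samples_a:
            own += group_a
        else:
            own += group_b
        ivs = []
        for chrom, pos in own:
            j = int(rng.integers(-jitter_bp, jitter_bp + 1)) if jitter_bp else 0
            ivs.append(GenomicInterval(chrom, pos + j, pos + j + peak_width))
        peaksets[s] = PeakSet(s, ivs)

    genes: list[GeneModel] = []
    n_genic = int(round(gene_fraction * total_slots))
    for k, (chrom, pos) in enumerate(slots[:n_genic]):
        # gene body starting just downstream of the slot so the peak sits
        # in the promoter window of a '+' gene, alternating with genes
        # containing the slot in the body
        if k % 2 == 0:
            start = pos + peak_width // 2 + 1000
            genes.append(
                GeneModel(f"G{k:04d}", chrom, "+", start, start + 5000,
                          [(start, start + 500)])
            )
        else:
            start = max(0, pos - 2000)
            genes.append(
                GeneModel(f"G{k:04d}", chrom, "+", start, start + 6000,
                          [(start, start + 300)])
            )
    region = lambda ch_pos: (ch_pos[0], ch_pos[1], ch_pos[1] + peak_width)
    truth = PeakLandscapeTruth(
        [region(s) for s in shared],
        [region(s) for s in group_a],
        [region(s) for s in group_b],
        samples_a,
        samples_b,
        seed,
    )
    return peaksets, genes, truth


# ---------------------------------------------------------------------------
# Negative-binomial counts


@dataclass
class CountTruth:
    differential_indices: list[int]
    fold_change: float
    dispersion: float
    baseline_mean: float
    seed: int

    def to_json(self, path) -> None:
        _truth_to_json(self, path)


def simulate_counts(
    regions: Sequence[GenomicInterval],
    design: GroupDesign,
    baseline_mean: float = 100.0,
    dispersion: float = 0.05,
    n_diff: int | None = None,
    fold_change: float = 4.0,
    library_sizes: Mapping[str, float] | None = None,
    diff_indices: Sequence[int] | None = None,
    seed: int = 0,
) -> tuple[CountMatrix, CountTruth]:
    """Negative-binomial fragment counts with planted differential regions.

    Counts have mean ``baseline_mean`` scaled by each sample's relative
    library size and variance mu + dispersion * mu^2; ``n_diff``
    randomly chosen regions (default 10%, or an explicit
    ``diff_indices`` list) have the fold change applied to group B.
    ``fold_change`` of 1 plants nothing.
    """
    if dispersion <= 0 or fold_change <= 0:
        raise ValueError("dispersion and fold_change must be positive")
    rng = np.random.default_rng(seed)
    samples = list(design.group_of.keys())
    n_r, n_s = len(regions), len(samples)
    if library_sizes is None:
        libs = rng.uniform(1.5e7, 2.5e7, size=n_s)
    else:
        libs = np.array([float(library_sizes[s]) for s in samples])
    rel = libs / np.exp(np.mean(np.log(libs)))  # geometric-mean scaling
    if diff_indices is not None:
        diff_idx = np.sort(np.asarray(diff_indices, dtype=int))
        n_diff = diff_idx.size
    else:
        if n_diff is None:
            n_diff = n_r // 10
        diff_idx = np.sort(rng.choice(n_r, size=n_diff, replace=False))
    if fold_change == 1.0:
        n_diff = 0
        diff_idx = diff_idx[:0]
    mask_b = np.array([design.group_of[s] == "B" for s in samples])
    mu = np.tile(baseline_mean * rel, (n_r, 1))
    if n_diff:
        mu[np.ix_(diff_idx, mask_b)] *= fold_change
    size = 1.0 / dispersion  # NB shape: var = mu + mu^2/size
    counts = rng.negative_binomial(size, size / (size + mu))
    cm = CountMatrix(list(regions), samples, counts, libs)
    truth = CountTruth(
        [int(i) for i in diff_idx], fold_change, dispersion, baseline_mean, seed
    )
    return cm, truth


# ---------------------------------------------------------------------------
# Time courses


@dataclass
class TimecourseTruth:
    up_genes: list[str]
    flat_genes: list[str]
    down_genes: list[str]
    amplitude: float
    noise_sd: float
    seed: int

    def to_json(self, path) -> None:
        _truth_to_json(self, path)


def simulate_timecourse(
    n_up: int = 40,
    n_flat: int = 50,
    n_down: int = 10,
    T: int = 6,
    amplitude: float = 1.0,
    noise_sd: float = 0.15,
    seed: int = 0,
) -> tuple[TimeCourse, TimecourseTruth]:
    """Log-ratio time course with planted up/flat/down temporal classes.

    Up genes rise monotonically to ``amplitude`` (linear in the
    timepoint index), down genes follow the negated profile, flat
    genes are pure noise; Gaussian noise is added at every timepoint
    except the first, which is identically 0 (ratios to time 0).
    """
    if T < 3:
        raise ValueError("need at least three timepoints")
    rng = np.random.default_rng(seed)
    base_up = amplitude * np.arange(T) / (T - 1)
    blocks = (
        [("U", base_up)] * n_up
        + [("F", np.zeros(T))] * n_flat
        + [("D", -base_up)] * n_down
    )
    genes, values, classes = [], [], []
    for k, (cls, base) in enumerate(blocks):
        noise = rng.normal(0.0, noise_sd, size=T)
        noise[0] = 0.0
        values.append(base + noise)
        genes.append(f"{cls}{k:04d}")
        classes.append(cls)
    values = np.asarray(values)
    timepoints = [float(t) for t in range(T)]
    tc = TimeCourse(genes, timepoints, values)
    classes = np.asarray(classes)
    garr = np.asarray(genes)
    truth = TimecourseTruth(
        list(garr[classes == "U"]),
        list(garr[classes == "F"]),
        list(garr[classes == "D"]),
        amplitude, noise_sd, seed,
    )
    return tc, truth


# ---------------------------------------------------------------------------
# Survival cohorts


@dataclass
class CohortTruth:
    signature_genes: list[str]
    beta: list[float]
    baseline_hazard: float
    censoring_rate: float
    realized_censoring: float
    linear_predictor: np.ndarray
    seed: int

    def to_json(self, path) -> None:
        _truth_to_json(self, path)


def simulate_cohort(
    n_patients: int = 131,
    n_genes: int = 49,
    signature: Mapping[str, float] | None = None,
    n_signature: int = 9,
    beta_range: tuple[float, float] = (0.5, 1.0),
    baseline_hazard: float = 0.01,
    censoring_rate: float = 0.75,
    clinical_model: str = "independent",
    gene_names: Sequence[str] | None = None,
    seed: int = 0,
) -> tuple[CohortData, CohortTruth]:
    """Expression + survival cohort driven by a planted gene subset.

    Expression is standard normal per gene; event times are exponential
    with rate baseline_hazard * exp(sum beta_i x_i); independent
    exponential censoring is calibrated so the expected censoring
    fraction matches ``censoring_rate``. ``signature`` maps gene names
    to true coefficients; if omitted, ``n_signature`` genes get
    alternating-sign coefficients drawn from ``beta_range``
    (``n_signature=0`` gives a pure-null cohort). ``clinical_model``
    'independent' draws clinical covariates independently;
    'confounded' ties the Gleason score to the linear predictor rank.
    """
    if not 0.0 <= censoring_rate < 1.0:
        raise ValueError("censoring_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    if gene_names is not None:
        if len(gene_names) != n_genes:
            raise ValueError("gene_names must have n_genes entries")
        genes = list(gene_names)
    else:
        genes = [f"GENE{j:04d}" for j in range(n_genes)]
    patients = [f"P{i:04d}" for i in range(n_patients)]
    X = rng.standard_normal((n_patients, n_genes))
    expr = pd.DataFrame(X, index=patients, columns=genes)

    if signature is None:
        if n_signature >= n_genes:
            raise ValueError("signature must be smaller than the gene panel")
        idx = rng.choice(n_genes, size=n_signature, replace=False)
        mags = rng.uniform(*beta_range, size=n_signature)
        signs = np.where(np.arange(n_signature) % 2 == 0, 1.0, -1.0)
        signature = {genes[j]: float(s * m)
                     for j, s, m in zip(idx, signs, mags)}
    missing = sorted(set(signature) - set(genes))
    if missing:
        raise ValueError(f"signature genes outside the panel: {missing}")

    beta_vec = np.zeros(n_genes)
    for g, b in signature.items():
        beta_vec[genes.index(g)] = b
    lp = X @ beta_vec
    rates = baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / rates)

    if censoring_rate > 0:
        # P(C < T_i) = c/(c + rate_i); calibrate c to the mean target
        def mean_censoring(c):
            return float(np.mean(c / (c + rates))) - censoring_rate

        lo, hi = 1e-9, 1e6
        c_rate = brentq(mean_censoring, lo, hi)
        t_cens = rng.exponential(1.0 / c_rate, size=n_patients)
    else:
        t_cens = np.full(n_patients, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    time = np.maximum(time, 1e-6)

    gleason_lv = np.array([6, 7, 8, 9])
    if clinical_model == "confounded":
        # Gleason increases with the linear-predictor rank
        qs = np.searchsorted(
            np.quantile(lp, [0.3, 0.75, 0.9]), lp, side="right"
        )
        gleason = gleason_lv[qs]
    elif clinical_model == "independent":
        gleason = rng.choice(gleason_lv, size=n_patients,
                             p=[0.30, 0.45, 0.15, 0.10])
    else:
        raise ValueError(f"unknown clinical_model {clinical_model!r}")
    clinical = pd.DataFrame(
        {
            "gleason": gleason,
            "pT": rng.choice(["T2a", "T2b", "T2c", "T3a", "T3b"],
                             size=n_patients, p=[0.2, 0.2, 0.3, 0.2, 0.1]),
            "pN": rng.choice([0, 1], size=n_patients, p=[0.85, 0.15]),
            "psa": np.exp(rng.normal(math.log(10.0), 0.6, size=n_patients)),
            "cT": rng.choice(["T1c", "T2a", "T2b", "T2c"],
                             size=n_patients, p=[0.4, 0.3, 0.2, 0.1]),
        },
        index=patients,
    )
    cohort = CohortData(expr, time, event, clinical)
    truth = CohortTruth(
        sorted(signature.keys()),
        [signature[g] for g in sorted(signature.keys())],
        baseline_hazard,
        censoring_rate,
        float(1.0 - event.mean()),
        lp,
        seed,
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# Coherent full-pipeline bundle


def simulate_discovery_bundle(
    out_dir,
    seed: int = 0,
    n_shared: int = 60,
    n_group_specific: int = 8,
    n_diff: int = 12,
    n_patients: int = 60,
    consensus_k: int = 3,
    n_signature: int = 3,
    noise_sd: float = 0.15,
) -> dict:
    """Write a coherent synthetic input bundle for the whole pipeline.

    The generated files share one gene universe: differential count
    regions are planted on consensus peaks, their proximal genes get
    planted temporal classes (the flat class carrying the survival
    signal), and the patient cohort's expression uses the same gene
    names — so the discovery pipeline can run end to end against known
    truth. Returns the config dict (also written as config.yaml) plus
    the planted truth.
    """
    from pathlib import Path

    import yaml

    from .intervals import (
        AnnotationParams,
        assign_peaks_to_genes,
        consensus_peaks,
        write_bed,
    )

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    peaksets, genes, ptruth = simulate_peak_landscape(
        n_shared=n_shared, n_group_specific=n_group_specific,
        gene_fraction=1.0, seed=seed,
    )
    peak_paths = {}
    for s, ps in peaksets.items():
        path = out / f"peaks_{s}.bed"
        write_bed(ps, path)
        peak_paths[s] = str(path)
    with open(out / "genes.bed12", "w") as fh:
        for g in genes:
            sizes = ",".join(str(e - s_) for s_, e in g.exons) + ","
            starts = ",".join(str(s_ - g.tx_start) for s_, e in g.exons) + ","
            fh.write(
                f"{g.chrom}\t{g.tx_start}\t{g.tx_end}\t{g.gene_id}\t0\t"
                f"{g.strand}\t{g.tx_start}\t{g.tx_end}\t0\t{len(g.exons)}\t"
                f"{sizes}\t{starts}\n"
            )
    ptruth.to_json(out / "truth_peaks.json")

    design = GroupDesign(
        {s: ("A" if s in ptruth.samples_a else "B") for s in peaksets}
    )
    consensus = consensus_peaks(list(peaksets.values()), consensus_k)
    diff_idx = np.sort(
        rng.choice(len(consensus), size=n_diff, replace=False)
    )
    cm, ctruth = simulate_counts(
        list(consensus), design, diff_indices=diff_idx, seed=seed + 1
    )
    cm.to_tsv(out / "counts.tsv")
    ctruth.to_json(out / "truth_counts.json")

    diff_regions = [consensus.intervals[i] for i in diff_idx]
    _, target_genes = assign_peaks_to_genes(
        diff_regions, genes, AnnotationParams()
    )

    # temporal classes: targets split up/flat/down, other genes flat noise
    all_genes = [g.gene_id for g in genes]
    classes = {g: "F" for g in all_genes}
    shuffled = list(target_genes)
    rng.shuffle(shuffled)
    n_t = len(shuffled)
    for g in shuffled[: int(0.4 * n_t)]:
        classes[g] = "U"
    for g in shuffled[int(0.4 * n_t) : int(0.6 * n_t)]:
        classes[g] = "D"
    T = 6
    base_up = np.arange(T) / (T - 1)
    values = []
    for g in all_genes:
        base = {"U": base_up, "D": -base_up, "F": np.zeros(T)}[classes[g]]
        noise = rng.normal(0, noise_sd, size=T)
        noise[0] = 0.0
        values.append(base + noise)
    tc = TimeCourse(all_genes, [float(t) for t in range(T)],
                    np.asarray(values))
    tc.to_tsv(out / "timecourse.tsv")

    flat_targets = [g for g in target_genes if classes[g] == "F"]
    sig_genes = flat_targets[:n_signature]
    signature = {
        g: (0.9 if i % 2 == 0 else -0.9) for i, g in enumerate(sig_genes)
    }
    cohort, htruth = simulate_cohort(
        n_patients=n_patients, n_genes=len(all_genes),
        signature=signature, gene_names=all_genes,
        censoring_rate=0.6, seed=seed + 2,
    )
    cohort.expression.T.rename_axis("gene").to_csv(
        out / "expression.tsv", sep="\t"
    )
    clin = cohort.clinical.copy()
    clin.insert(0, "time_months", cohort.time)
    clin.insert(1, "event", cohort.event)
    clin.rename_axis("patient").to_csv(out / "clinical.tsv", sep="\t")
    htruth.to_json(out / "truth_cohort.json")

    config = {
        "output_dir": str(out / "results"),
        "peaks_bed": peak_paths,
        "counts_tsv": str(out / "counts.tsv"),
        "gene_models": str(out / "genes.bed12"),
        "timecourse_tsv": str(out / "timecourse.tsv"),
        "expression_tsv": str(out / "expression.tsv"),
        "clinical_tsv": str(out / "clinical.tsv"),
        "groups": dict(design.group_of),
        "consensus_min_samples": consensus_k,
        "n_lambdas": 25,
        "lambda_min_ratio": 0.1,
        "seed": seed,
    }
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return {
        "config": config,
        "target_genes": target_genes,
        "classes": classes,
        "signature": signature,
        "diff_indices": [int(i) for i in diff_idx],
    }
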