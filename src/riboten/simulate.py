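"""Synthetic ribosome-profiling experiments with known ground truth.

The generator emulates a two-condition (WT vs mutant), two-replicate
footprint + total-RNA experiment in a yeast-like transcriptome:

* ORF lengths log-normal (median 1200 nt), multiples of 3, >= 150 nt;
* relative mRNA abundances log-normal and, by default, independent of
  length (a length-abundance coupling knob exists);
* WT TE declining with ORF length (short ORFs are the best-translated);
* a planted TE change (dTE) whose log2 value rises linearly with log10
  ORF length plus per-gene scatter — the mutant hits short ORFs hardest —
  with optional extra log2 shifts on named gene groups;
* counts negative-binomial around depth x abundance x (TE for footprint
  libraries), dispersion 0 meaning Poisson;
* read-level 28-nt alignments placed uniformly inside each gene's legal
  counting window, plus configurable decoy reads (multi-mappers or
  out-of-window placements) that positional counting must reject;
* multi-peak A254 gradient traces as Gaussians over a linear baseline.

Everything is deterministic under ``config.seed``; each stage draws from
its own child stream so stages can be re-run independently.

No nucleotide sequences are simulated; positions and counts only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .annotation import AnnotationSet, TranscriptAnnotation
from .counting import CountMatrix, DEFAULT_OFFSETS, Offsets, ReadAlignment, counting_window
from .errors import ConfigurationError

__all__ = [
    "GroupDef",
    "SimulationConfig",
    "TrueState",
    "TraceSimSpec",
    "simulate_annotation",
    "simulate_truth",
    "simulate_counts",
    "simulate_reads",
    "simulate_trace",
    "simulate_experiment",
    "default_polysome_spec",
]

# child-stream tags so each stage has an independent deterministic stream
_STREAMS = {"annotation": 11, "truth": 12, "counts": 13, "reads": 14, "trace": 15}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stage]])


@dataclass(frozen=True)
class GroupDef:
    """A planted gene group: selection rule plus an extra log2 dTE shift.

    Select either by explicit ``gene_ids`` or by an ORF-length quantile
    range ``[q_lo, q_hi)`` (e.g. (0.0, 0.1) = shortest decile), optionally
    subsampled to ``size`` members.
    """

    name: str
    quantile_range: Optional[tuple[float, float]] = None
    gene_ids: Optional[tuple[str, ...]] = None
    size: Optional[int] = None
    extra_shift_log2: float = 0.0

    def __post_init__(self) -> None:
        if (self.quantile_range is None) == (self.gene_ids is None):
            raise ConfigurationError(
                f"group {self.name!r}: give exactly one of quantile_range or gene_ids"
            )


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic experiment.

    Length/TE slopes are log2 units per decade (log10) of ORF length;
    sigmas are natural-log scale for log-normal draws except the two TE
    scatters, which are log2. Defaults give a planted Spearman(dTE,
    log10 L) around 0.27 at the default scatter.
    """

    n_genes: int = 4000
    orf_length_median: float = 1200.0
    orf_length_sigma: float = 0.65
    utr5_median: float = 60.0
    utr3_median: float = 120.0
    utr_sigma: float = 0.5
    abundance_sigma: float = 1.0
    length_abundance_slope: float = 0.0
    wt_te_length_slope: float = -0.6
    wt_te_sigma: float = 0.5
    dte_length_slope: float = 0.55
    dte_sigma: float = 0.55
    group_defs: tuple[GroupDef, ...] = ()
    nb_dispersion: float = 0.01
    library_depth: float = 5e6
    n_replicates: int = 2
    conditions: tuple[str, str] = ("WT", "mut")
    read_length: int = 28
    min_orf_length: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 0:
            raise ConfigurationError("n_genes must be >= 0")
        if self.orf_length_median <= 0 or self.orf_length_sigma <= 0:
            raise ConfigurationError("invalid ORF length distribution parameters")
        if self.library_depth <= 0:
            raise ConfigurationError("library_depth must be > 0")
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be >= 0")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")

    def library_ids(self) -> list[str]:
        return [
            f"{assay}:{cond}:rep{i}"
            for assay in ("FP", "total")
            for cond in self.conditions
            for i in range(1, self.n_replicates + 1)
        ]


@dataclass
class TrueState:
    """Planted ground truth: per-gene table, group memberships, expected means.

    ``genes`` columns: orf_length, transcript_length, abundance, te_wt,
    dte_log2 (group shifts already included). ``expected_means`` is genes x
    library ids, consistent with depth x abundance x TE factorization.
    """

    genes: pd.DataFrame
    groups: dict[str, list[str]]
    expected_means: pd.DataFrame

    def to_tsv(self, path) -> None:
        out = self.genes.copy()
        for name, members in self.groups.items():
            out[f"group_{name}"] = out.index.isin(members).astype(int)
        out.to_csv(path, sep="\t", index_label="gene_id", float_format="%.8g")


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(max(n - 1, 0))))
    return [f"g{i:0{width}d}" for i in range(n)]


def simulate_annotation(config: SimulationConfig) -> AnnotationSet:
    """Draw one transcript model per gene.

    ORF lengths are log-normal, rounded to a multiple of 3 and floored at
    ``min_orf_length`` (150 nt by default, so the 30-codon exclusion never
    empties the counting window); the ORF sits right after the 5' UTR.
    """
    rng = _rng(config.seed, "annotation")
    n = config.n_genes
    raw = rng.lognormal(math.log(config.orf_length_median), config.orf_length_sigma, n)
    orf_len = np.maximum(3 * np.round(raw / 3).astype(int), config.min_orf_length)
    utr5 = np.round(
        rng.lognormal(math.log(config.utr5_median), config.utr_sigma, n)
    ).astype(int)
    utr3 = np.round(
        rng.lognormal(math.log(config.utr3_median), config.utr_sigma, n)
    ).astype(int)
    utr5 = np.maximum(utr5, 1)
    utr3 = np.maximum(utr3, 1)
    return AnnotationSet(
        TranscriptAnnotation(
            gene_id=g,
            transcript_length=int(utr5[i] + orf_len[i] + utr3[i]),
            orf_start=int(utr5[i]),
            orf_end=int(utr5[i] + orf_len[i]),
        )
        for i, g in enumerate(_gene_ids(n))
    )


def _select_group(
    gdef: GroupDef, lengths: pd.Series, rng: np.random.Generator
) -> list[str]:
    if gdef.gene_ids is not None:
        members = [g for g in gdef.gene_ids if g in lengths.index]
    else:
        lo_q, hi_q = gdef.quantile_range
        lo = lengths.quantile(lo_q) if lo_q > 0 else -np.inf
        hi = lengths.quantile(hi_q) if hi_q < 1 else np.inf
        members = list(lengths.index[(lengths >= lo) & (lengths < hi)])
    if gdef.size is not None and len(members) > gdef.size:
        members = sorted(rng.choice(members, size=gdef.size, replace=False))
    return members


def simulate_truth(config: SimulationConfig, annotation: AnnotationSet) -> TrueState:
    """Plant per-gene abundances, WT TE, dTE (with group shifts) and the
    per-library expected mean counts they imply."""
    rng = _rng(config.seed, "truth")
    lengths = annotation.orf_lengths().astype(float)
    tlen = annotation.transcript_lengths().astype(float)
    n = len(lengths)
    z = np.log10(lengths) - float(np.log10(lengths).mean()) if n else lengths * 0.0

    log2_abund = config.abundance_sigma / math.log(2) * rng.standard_normal(n)
    log2_abund += config.length_abundance_slope * z
    abundance = np.exp2(log2_abund)

    te_wt = np.exp2(
        config.wt_te_length_slope * z + config.wt_te_sigma * rng.standard_normal(n)
    )
    dte_log2 = pd.Series(
        config.dte_length_slope * z.to_numpy()
        + config.dte_sigma * rng.standard_normal(n),
        index=lengths.index,
    )

    groups: dict[str, list[str]] = {}
    for gdef in config.group_defs:
        members = _select_group(gdef, lengths, rng)
        groups[gdef.name] = members
        dte_log2.loc[members] += gdef.extra_shift_log2

    genes = pd.DataFrame(
        {
            "orf_length": lengths.astype(int),
            "transcript_length": tlen.astype(int),
            "abundance": abundance,
            "te_wt": te_wt,
            "dte_log2": dte_log2,
        }
    )
    genes.index.name = "gene_id"

    means = {}
    wt_cond, mut_cond = config.conditions
    for lib in config.library_ids():
        assay, cond, _ = lib.split(":")
        if assay == "total":
            weights = abundance
        else:
            te = te_wt * (np.exp2(dte_log2.to_numpy()) if cond == mut_cond else 1.0)
            weights = abundance * te
        total_w = weights.sum()
        means[lib] = config.library_depth * weights / total_w if total_w > 0 else weights
    expected = pd.DataFrame(means, index=genes.index)
    return TrueState(genes=genes, groups=groups, expected_means=expected)


def simulate_counts(config: SimulationConfig, truth: TrueState) -> CountMatrix:
    """Negative-binomial counts around the expected means (Poisson at
    dispersion 0). Variance is mu + dispersion * mu^2."""
    rng = _rng(config.seed, "counts")
    alpha = config.nb_dispersion
    cols = {}
    for lib in truth.expected_means.columns:
        mu = truth.expected_means[lib].to_numpy(float)
        if alpha == 0:
            cols[lib] = rng.poisson(mu)
        else:
            size = 1.0 / alpha
            p = size / (size + mu)
            cols[lib] = rng.negative_binomial(size, p)
    return CountMatrix(pd.DataFrame(cols, index=truth.expected_means.index))


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[AnnotationSet, TrueState, CountMatrix]:
    """Annotation, planted truth and count matrix in one call."""
    annotation = simulate_annotation(config)
    truth = simulate_truth(config, annotation)
    counts = simulate_counts(config, truth)
    return annotation, truth, counts


def simulate_reads(
    annotation: AnnotationSet,
    counts: pd.Series,
    contamination_frac: float = 0.0,
    read_length: int = 28,
    offsets: Offsets = DEFAULT_OFFSETS,
    seed: int = 0,
) -> list[ReadAlignment]:
    """Read-level alignments realizing one library's counts.

    Each counted read becomes a unique ``read_length``-nt alignment whose
    5' end is uniform over the placements fully inside the gene's counting
    window, so positional counting recovers ``counts`` exactly. On top,
    ``contamination_frac`` of the total is added as decoy reads — either
    multi-mapping (inside the window, unique=False) or unique but violating
    containment — all of which counting must reject. Genes whose window
    cannot hold a read are skipped with a warning.
    """
    rng = _rng(seed, "reads")
    reads: list[ReadAlignment] = []
    placeable: list[str] = []
    for gene_id, k in counts.items():
        ann = annotation[gene_id]
        win = counting_window(ann, offsets)
        if win is None or win[1] - win[0] < read_length:
            if k > 0:
                warnings.warn(
                    f"simulate_reads: window of {gene_id} cannot hold a "
                    f"{read_length}-nt read; {k} reads skipped"
                )
            continue
        placeable.append(gene_id)
        if k > 0:
            starts = rng.integers(win[0], win[1] - read_length + 1, size=int(k))
            reads.extend(
                ReadAlignment(gene_id, int(s), int(s) + read_length, True)
                for s in starts
            )

    n_decoys = int(round(contamination_frac * len(reads)))
    if n_decoys and placeable:
        decoy_genes = rng.choice(placeable, size=n_decoys, replace=True)
        for gene_id in decoy_genes:
            ann = annotation[gene_id]
            win = counting_window(ann, offsets)
            # violating starts: 5' of the window start, or 3' overhang
            lo_region = range(0, min(win[0], ann.transcript_length - read_length))
            hi_region = range(
                max(win[1] - read_length + 1, 0), ann.transcript_length - read_length + 1
            )
            make_multi = rng.random() < 0.5
            if not make_multi and (len(lo_region) or len(hi_region)):
                pick = rng.integers(0, len(lo_region) + len(hi_region))
                start = (
                    lo_region[pick]
                    if pick < len(lo_region)
                    else hi_region[pick - len(lo_region)]
                )
                reads.append(
                    ReadAlignment(gene_id, int(start), int(start) + read_length, True)
                )
            else:
                start = int(rng.integers(win[0], win[1] - read_length + 1))
                reads.append(
                    ReadAlignment(gene_id, start, start + read_length, False)
                )
    order = rng.permutation(len(reads))
    return [reads[i] for i in order]


@dataclass(frozen=True)
class TraceSimSpec:
    """Gaussian-mixture A254 trace: sum of peaks over a linear baseline.

    ``areas`` are analytic areas (absorbance x position units) and are the
    ground truth for integration tests; ``widths`` are Gaussian sigmas.
    """

    centers: tuple[float, ...]
    areas: tuple[float, ...]
    widths: tuple[float, ...]
    baseline_slope: float = 0.0
    baseline_intercept: float = 0.0
    noise_sd: float = 0.0
    n_samples: int = 2000
    x_min: float = 0.0
    x_max: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (len(self.centers) == len(self.areas) == len(self.widths)):
            raise ConfigurationError("centers/areas/widths lengths differ")
        if any(np.diff(self.centers) <= 0):
            raise ConfigurationError("peak centers must be strictly increasing")
        if any(w <= 0 for w in self.widths):
            raise ConfigurationError("peak widths must be > 0")
        if any(a < 0 for a in self.areas):
            raise ConfigurationError("peak areas must be >= 0")
        if self.n_samples < 16:
            raise ConfigurationError("n_samples must be >= 16")


def simulate_trace(spec: TraceSimSpec):
    """Sample the trace on a uniform grid; returns (PolysomeTrace, truth areas)."""
    from .trace import PolysomeTrace  # local import to avoid cycle at import time

    rng = _rng(spec.seed, "trace")
    x = np.linspace(spec.x_min, spec.x_max, spec.n_samples)
    y = spec.baseline_intercept + spec.baseline_slope * x
    for c, a, w in zip(spec.centers, spec.areas, spec.widths):
        y = y + a / (w * math.sqrt(2 * math.pi)) * np.exp(-0.5 * ((x - c) / w) ** 2)
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, spec.n_samples)
    return PolysomeTrace(x, y), np.array(spec.areas, dtype=float)


def default_polysome_spec(seed: int = 0, noise_sd: float = 0.0) -> TraceSimSpec:
    """A plausible yeast profile: 40S < 60S < dominant 80S, tapering polysomes."""
    return TraceSimSpec(
        centers=(3.0, 4.4, 6.2, 8.6, 10.6, 12.6, 14.6),
        areas=(0.5, 0.9, 3.0, 2.2, 1.5, 0.9, 0.5),
        widths=(0.32, 0.34, 0.45, 0.5, 0.55, 0.6, 0.65),
        baseline_slope=0.002,
        baseline_intercept=0.05,
        noise_sd=noise_sd,
        n_samples=2000,
        x_min=0.0,
        x_max=18.0,
        seed=seed,
    )
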