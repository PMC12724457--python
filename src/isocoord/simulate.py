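"""Seeded generators for every input the pipeline consumes, with truth.

The coordination generator draws inclusion counts from the same logit
law the nested GLMs assume:

    logit P(inclusion | site j, time t) = mu + alpha_j + beta_t + gamma_jt

with per-(site, sample) totals Poisson around a target depth and
optional beta-binomial overdispersion rho (rho = 0 recovers binomial
sampling; Pearson dispersion grows as ~ 1 + (n-1) rho, which is the
calibration handle the quasi-likelihood correction exists for). Variant
tables draw singleton indicators Bernoulli around a linear
mutability baseline plus class-specific shifts, and expression tables
draw log2FC/FDR pairs consistent with known trajectory codes. Every
generator is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .events import EventCountTable
from .genome import GenomicInterval, TranscriptModel

__all__ = [
    "SimulationConfig",
    "CoordinationTruth",
    "make_truths",
    "simulate_event_counts",
    "gen_transcript_models",
    "gen_transcript_counts",
    "gen_variant_table",
    "gen_expression_tables",
    "gen_te_table",
    "default_mutability_table",
]

DEFAULT_TIMEPOINTS = ("t00", "t04", "t30")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-scale defaults: 200 events, 3 timepoints x 3 samples, 2 polyA
    sites per event, expected depth 100 reads per (site, sample)."""

    n_events: int = 200
    sites_per_event: int = 2
    samples_per_timepoint: int = 3
    timepoints: tuple[str, ...] = DEFAULT_TIMEPOINTS
    depth: float = 100.0
    rho: float = 0.0
    seed: int = 0
    site_spacing: int = 200  # nt between neighbouring end sites (> 24)

    def __post_init__(self) -> None:
        if self.rho < 0 or self.rho >= 1:
            raise ValueError("rho must lie in [0, 1)")
        if min(self.n_events, self.sites_per_event, self.samples_per_timepoint) < 1:
            raise ValueError("all counts must be >= 1")
        if self.depth <= 0:
            raise ValueError("depth must be positive")

    @property
    def samples(self) -> list[str]:
        return [
            f"{tp}_r{r + 1}"
            for tp in self.timepoints
            for r in range(self.samples_per_timepoint)
        ]

    @property
    def sample_timepoint(self) -> dict[str, str]:
        return {s: s.split("_")[0] for s in self.samples}


@dataclass(frozen=True)
class CoordinationTruth:
    """Generating parameters of one event, with derived truth flags."""

    event_id: str
    gene_id: str
    mu: float
    alpha_site: tuple[float, ...]
    beta_time: tuple[float, ...]
    gamma: tuple[tuple[float, ...], ...]  # [site][time]
    rho: float
    depth: float

    @property
    def true_global(self) -> bool:
        return any(a != 0.0 for a in self.alpha_site)

    @property
    def true_interaction(self) -> bool:
        return any(g != 0.0 for row in self.gamma for g in row)

    def inclusion_probability(self) -> np.ndarray:
        """P(inclusion) per (site, time) cell."""
        a = np.asarray(self.alpha_site)[:, None]
        b = np.asarray(self.beta_time)[None, :]
        g = np.asarray(self.gamma)
        eta = self.mu + a + b + g
        return 1.0 / (1.0 + np.exp(-eta))


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def make_truths(
    config: SimulationConfig,
    kind: str = "null",
    delta_psi: float = 0.3,
    baseline_psi: float = 0.35,
) -> list[CoordinationTruth]:
    """Truth records for `n_events` events of one coordination kind.

    ``null``: no site or interaction effect (alpha = gamma = 0).
    ``global``: a stable site effect — the last site's inclusion
    probability sits `delta_psi` above `baseline_psi` at every timepoint.
    ``interaction``: a purely time-dependent effect — the last site moves
    from `baseline - delta/2` to `baseline + delta/2` across the time
    course so its time-average matches the other sites (no net global
    spread), which only the interaction model can capture.
    """
    if kind not in ("null", "global", "interaction"):
        raise ValueError(f"unknown truth kind {kind!r}")
    n_sites = config.sites_per_event
    n_times = len(config.timepoints)
    mu = _logit(baseline_psi)
    alpha = [0.0] * n_sites
    gamma = [[0.0] * n_times for _ in range(n_sites)]
    if kind == "global":
        alpha[-1] = _logit(baseline_psi + delta_psi) - mu
    elif kind == "interaction":
        offsets = np.linspace(-delta_psi / 2, delta_psi / 2, n_times)
        gamma[-1] = [_logit(baseline_psi + o) - mu for o in offsets]
    truths = []
    for i in range(config.n_events):
        gene = f"g{kind[0].upper()}{i:04d}"
        truths.append(
            CoordinationTruth(
                event_id=f"{gene}:ev",
                gene_id=gene,
                mu=mu,
                alpha_site=tuple(alpha),
                beta_time=tuple([0.0] * n_times),
                gamma=tuple(tuple(row) for row in gamma),
                rho=config.rho,
                depth=config.depth,
            )
        )
    return truths


def _beta_binomial(
    rng: np.random.Generator, n: np.ndarray, p: np.ndarray, rho: float
) -> np.ndarray:
    if rho == 0.0:
        return rng.binomial(n, p)
    a = p * (1.0 - rho) / rho
    b = (1.0 - p) * (1.0 - rho) / rho
    return rng.binomial(n, rng.beta(a, b, size=np.shape(n)))


def simulate_event_counts(
    truths: list[CoordinationTruth], config: SimulationConfig
) -> EventCountTable:
    """Draw the per-(event, site, sample) inclusion/skipping count table."""
    rng = np.random.default_rng(config.seed)
    samples = config.samples
    tp_index = {s: config.timepoints.index(tp) for s, tp in config.sample_timepoint.items()}
    rows = []
    for truth in truths:
        prob = truth.inclusion_probability()
        for j in range(config.sites_per_event):
            cluster = f"{truth.gene_id}:pA{j + 1}"
            for sample in samples:
                t = tp_index[sample]
                total = max(int(rng.poisson(truth.depth)), 1)
                p = np.full((), prob[j, t])
                inc = int(_beta_binomial(rng, np.full((), total), p, truth.rho))
                rows.append(
                    {
                        "event_id": truth.event_id,
                        "gene_id": truth.gene_id,
                        "cluster_id": cluster,
                        "sample_id": sample,
                        "inclusion_count": inc,
                        "skipping_count": total - inc,
                    }
                )
    return EventCountTable(
        data=pd.DataFrame(rows), sample_timepoint=config.sample_timepoint
    )


def _reflect(models: list[TranscriptModel]) -> list[TranscriptModel]:
    """Mirror a gene's + strand geometry onto the - strand."""
    hi = max(m.exons[-1].end for m in models)
    lo = min(m.exons[0].start for m in models)
    span = lo + hi

    def flip(iv: GenomicInterval) -> GenomicInterval:
        return GenomicInterval(iv.chrom, span - iv.end, span - iv.start, "-")

    out = []
    for m in models:
        out.append(
            TranscriptModel(
                transcript_id=m.transcript_id,
                gene_id=m.gene_id,
                exons=[flip(e) for e in m.exons],
                strand="-",
                cds_span=flip(m.cds_span) if m.cds_span else None,
            )
        )
    return out


def gen_transcript_models(
    truths: list[CoordinationTruth],
    config: SimulationConfig,
    minus_strand_fraction: float = 0.5,
) -> list[TranscriptModel]:
    """Gene geometries realizing each truth record.

    Each gene carries one skippable internal exon and
    ``sites_per_event`` end sites spaced ``site_spacing`` nt apart
    (default 200 nt, beyond the 24-nt clustering window), yielding an
    inclusion and a skipping isoform per end site. A CDS spanning the
    first through penultimate exon keeps the alternative exon inside the
    ORF. A seeded fraction of genes is mirrored to the - strand.
    """
    rng = np.random.default_rng(config.seed + 1)
    exon_len, intron_len = 150, 850
    models: list[TranscriptModel] = []
    for gi, truth in enumerate(truths):
        chrom = f"chrS{gi % 4 + 1}"
        n_ex = int(rng.integers(5, 9))
        offset = 10_000 + gi * 50_000
        starts = [offset + k * (exon_len + intron_len) for k in range(n_ex)]
        exons = [
            GenomicInterval(chrom, s, s + exon_len, "+") for s in starts
        ]
        as_idx = n_ex // 2
        cds = GenomicInterval(
            chrom, exons[0].start + 30, exons[-2].end - 30, "+"
        )
        gene_models = []
        for j in range(config.sites_per_event):
            last = GenomicInterval(
                chrom,
                exons[-1].start,
                exons[-1].end + j * config.site_spacing,
                "+",
            )
            body = exons[:-1] + [last]
            for label, keep in (("inc", True), ("skp", False)):
                used = [
                    e for i, e in enumerate(body) if keep or i != as_idx
                ]
                gene_models.append(
                    TranscriptModel(
                        transcript_id=f"{truth.gene_id}_pA{j + 1}_{label}",
                        gene_id=truth.gene_id,
                        exons=used,
                        strand="+",
                        cds_span=cds,
                    )
                )
        if rng.random() < minus_strand_fraction:
            gene_models = _reflect(gene_models)
        models.extend(gene_models)
    return models


def gen_transcript_counts(
    table: EventCountTable, truths: list[CoordinationTruth]
) -> pd.DataFrame:
    """Project an event count table onto the generated isoforms.

    The inclusion transcript of (gene, site) receives the cell's
    inclusion count and the skipping transcript the skipping count, giving
    a transcript-by-sample matrix whose event reconstruction is exact.
    """
    samples = sorted(set(table.data["sample_id"]), key=list(table.data["sample_id"]).index)
    rows: dict[str, dict[str, int]] = {}
    for r in table.data.itertuples():
        site = r.cluster_id.split(":")[-1]
        inc_id = f"{r.gene_id}_{site}_inc"
        skp_id = f"{r.gene_id}_{site}_skp"
        rows.setdefault(inc_id, {})[r.sample_id] = r.inclusion_count
        rows.setdefault(skp_id, {})[r.sample_id] = r.skipping_count
    out = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    return out.reindex(sorted(out.index), columns=samples)


def default_mutability_table(n_contexts: int = 16) -> pd.DataFrame:
    """Synthetic trinucleotide mutability table (context, mu).

    Context labels are synthetic stand-ins for trinucleotide+allele keys;
    mu spans the 2e-8..1.6e-7 range typical of per-site SNV rates.
    """
    mus = np.linspace(2e-8, 1.6e-7, n_contexts)
    return pd.DataFrame(
        {"context": [f"ctx{i:02d}" for i in range(n_contexts)], "mu": mus}
    )


def gen_variant_table(
    n_per_class: dict[str, int],
    class_shifts: dict[str, float],
    seed: int,
    mutability: pd.DataFrame | None = None,
    base_intercept: float = 0.25,
    base_slope: float = 1.5e6,
) -> pd.DataFrame:
    """Variant table with class-specific singleton-proportion shifts.

    Per class, contexts are drawn with probability proportional to mu and
    singleton flags Bernoulli(intercept + slope*mu + shift), clipped to
    [0, 1] with a warning when a shift escapes the unit interval.
    """
    import warnings

    rng = np.random.default_rng(seed)
    if mutability is None:
        mutability = default_mutability_table()
    mu = mutability["mu"].to_numpy()
    ctx = mutability["context"].to_numpy()
    weights = mu / mu.sum()
    frames = []
    for name, n in n_per_class.items():
        shift = class_shifts.get(name, 0.0)
        idx = rng.choice(len(ctx), size=n, p=weights)
        prob = base_intercept + base_slope * mu[idx] + shift
        if (prob < 0).any() or (prob > 1).any():
            warnings.warn(
                f"class {name}: singleton probability clipped to [0, 1]",
                stacklevel=2,
            )
            prob = np.clip(prob, 0.0, 1.0)
        frames.append(
            pd.DataFrame(
                {
                    "variant_id": [f"{name}_{i}" for i in range(n)],
                    "context": ctx[idx],
                    "variant_class": name,
                    "is_singleton": rng.random(n) < prob,
                    "mu": mu[idx],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def gen_expression_tables(
    n_per_code: int, seed: int, codes: tuple[str, ...] | None = None
) -> pd.DataFrame:
    """log2FC/FDR tables whose true trajectory codes are known.

    Values are drawn strictly inside each code's defining region with a
    margin away from the |log2FC| = 1 and FDR = 0.05 boundaries, so
    reclassification recovers the labels exactly and is robust to float
    noise.
    """
    from .dynamics import TRAJECTORY_CODES

    rng = np.random.default_rng(seed)
    codes = codes or TRAJECTORY_CODES

    def draw(symbol: str) -> tuple[float, float]:
        if symbol == "U":
            return float(rng.uniform(1.2, 3.5)), float(rng.uniform(1e-4, 0.04))
        if symbol == "D":
            return float(-rng.uniform(1.2, 3.5)), float(rng.uniform(1e-4, 0.04))
        return float(rng.uniform(-0.85, 0.85)), float(rng.uniform(0.0, 1.0))

    rows = []
    for code in codes:
        for i in range(n_per_code):
            lfc1, fdr1 = draw(code[0])
            lfc2, fdr2 = draw(code[1])
            rows.append(
                {
                    "unit_id": f"{code}_{i:04d}",
                    "lfc1": lfc1,
                    "fdr1": fdr1,
                    "lfc2": lfc2,
                    "fdr2": fdr2,
                    "true_code": code,
                }
            )
    return pd.DataFrame(rows)


def gen_te_table(
    n_per_class: int,
    seed: int,
    cds_density: float = 5.0,
    n_replicates: int = 3,
    mean_input: float = 100.0,
) -> pd.DataFrame:
    """RPF/input counts where CDS regions get `cds_density`-fold the
    ribosome footprint density of 3'UTR regions."""
    rng = np.random.default_rng(seed)
    rows = []
    for te_class, density in (("CDS", cds_density), ("3UTR", 1.0)):
        for i in range(n_per_class):
            inp = rng.poisson(mean_input, n_replicates) + 6
            rpf = rng.poisson(0.5 * density * inp)
            rows.append(
                {
                    "region_id": f"{te_class}_{i:04d}",
                    "te_class": te_class,
                    **{f"rpf_{r + 1}": int(rpf[r]) for r in range(n_replicates)},
                    **{f"input_{r + 1}": int(inp[r]) for r in range(n_replicates)},
                }
            )
    return pd.DataFrame(rows)
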