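"""Synthetic-data generator for the neural-axis pipeline.

Every input the pipeline consumes is generated here with known ground truth:
probe-level microarray intensities for the four ordered tissues (SZ, PNT,
CNT, RNT) with a planted "switch" cohort whose expression steps between PNT
and CNT, probe-set → gene annotation with deliberate gaps closeable by EST
chains, cross-species ortholog tables with 1:1 / 1:many / many:many cases on
toy ordered chromosomes, GMT term sets, 3'-biased read alignments extending
past truncated gene annotations, and per-section binomial EdU / pH3 counts
from the cumulative-labeling model L(t) = (S + t)/T.

All randomness flows from one `numpy.random.default_rng` stream seeded from
``SimulationConfig.seed``, so a fixed seed fixes every emitted byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io

TISSUES = ("SZ", "PNT", "CNT", "RNT")

#: Planted cell-cycle parameters (T hours, S hours) per region.  SZ and RNT
#: anchor at a total cycle time of ~8 h and ~16 h with S-phase lengths of 3 h
#: and 4 h; PNT and CNT interpolate monotonically between them.
DEFAULT_CELL_CYCLE = {
    "SZ": (8.0, 3.0),
    "PNT": (10.0, 3.3),
    "CNT": (13.0, 3.7),
    "RNT": (16.0, 4.0),
}


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic microarray experiment.

    Defaults mirror the study conditions: four tissues in fixed axial order
    with three biological replicates each, a switch cohort of 20% of
    probe-sets of which 64% are downregulated across the PNT → CNT
    transition, a one log2-unit step, and a 35% vendor-annotation gap that
    EST evidence can close to 16%.
    """

    n_tissues: int = 4
    n_replicates: int = 3
    n_probesets: int = 1000
    probes_per_probeset: int = 11
    switch_fraction: float = 0.2
    down_fraction: float = 0.64
    marker_fraction: float = 0.1
    effect_size: float = 1.0
    noise_sd: float = 0.25
    annotation_gap: float = 0.35
    residual_gap: float = 0.16
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tissues != len(TISSUES):
            raise ValueError(f"n_tissues must be {len(TISSUES)} (fixed order {TISSUES})")
        for name in ("n_replicates", "n_probesets", "probes_per_probeset"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in (
            "switch_fraction",
            "down_fraction",
            "marker_fraction",
            "annotation_gap",
            "residual_gap",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.residual_gap > self.annotation_gap:
            raise ValueError("residual_gap cannot exceed annotation_gap")
        if self.switch_fraction + self.marker_fraction > 1:
            raise ValueError("switch_fraction + marker_fraction cannot exceed 1")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class ProbeIntensityMatrix:
    """Raw probe × sample intensities plus chip layout and sample sheet."""

    intensities: pd.DataFrame  # probe_id × sample_id, positive values
    layout: pd.Series  # probe_id → probeset_id
    samples: pd.DataFrame  # indexed by sample_id; columns tissue, replicate

    def __post_init__(self) -> None:
        if (self.intensities.values <= 0).any():
            raise ValueError("intensities must be strictly positive")
        if self.intensities.shape[1] < 2:
            raise ValueError("need at least two samples")
        missing = set(self.intensities.index) - set(self.layout.index)
        if missing:
            raise ValueError(f"{len(missing)} probes missing from layout")


@dataclass
class GroundTruth:
    """Planted truth for every generated input (filled per generator)."""

    probesets: pd.DataFrame | None = None  # is_switch, direction, mean_<tissue>
    gene_map: pd.Series | None = None  # probeset_id → true gene
    ortholog_truth: pd.DataFrame | None = None  # gene_A, gene_B true pairs
    enriched_terms: list[str] = field(default_factory=list)
    cell_cycle: dict[str, tuple[float, float]] = field(default_factory=dict)
    utr_extensions: pd.Series | None = None  # gene_id → planted extension (bp)
    true_models: pd.DataFrame | None = None
    drs_expression: pd.Series | None = None  # gene_id → expression used for reads

    def to_json(self, path) -> None:
        blob: dict = {"enriched_terms": self.enriched_terms}
        if self.probesets is not None:
            blob["probesets"] = self.probesets.reset_index().to_dict(orient="list")
        if self.gene_map is not None:
            blob["gene_map"] = self.gene_map.to_dict()
        if self.ortholog_truth is not None:
            blob["ortholog_truth"] = self.ortholog_truth.to_dict(orient="list")
        if self.cell_cycle:
            blob["cell_cycle"] = {k: list(v) for k, v in self.cell_cycle.items()}
        if self.utr_extensions is not None:
            blob["utr_extensions"] = self.utr_extensions.to_dict()
        if self.drs_expression is not None:
            blob["drs_expression"] = self.drs_expression.to_dict()
        if self.true_models is not None:
            blob["true_models"] = self.true_models.to_dict(orient="list")
        with open(path, "w") as fh:
            json.dump(blob, fh, indent=1, sort_keys=True)


def _probeset_ids(n: int) -> list[str]:
    return [f"PS{i:05d}" for i in range(n)]


def _sample_sheet(n_replicates: int) -> pd.DataFrame:
    rows = [
        {"sample_id": f"{t}_{r + 1}", "tissue": t, "replicate": r + 1}
        for t in TISSUES
        for r in range(n_replicates)
    ]
    return pd.DataFrame(rows).set_index("sample_id")


def simulate_probe_intensities(
    config: SimulationConfig, zero_noise: bool = False, rng: np.random.Generator | None = None
) -> tuple[ProbeIntensityMatrix, GroundTruth]:
    """Simulate raw probe intensities with a planted PNT→CNT switch cohort.

    Probe-level intensity is 2**(tissue_mean + probe_affinity + noise) with
    probe affinities drawn once per probe (Normal(0, 1) log2 units, shared
    across samples — the additive probe effect median polish assumes) and
    i.i.d. Gaussian log2 noise.  Planted switch probe-sets differ only
    between PNT and CNT: mean(CNT) = mean(RNT) = mean(SZ) ± effect_size.
    """
    rng = config.rng() if rng is None else rng
    n = config.n_probesets
    ps_ids = _probeset_ids(n)

    base = rng.normal(config.baseline_mean, config.baseline_sd, n)
    n_switch = int(round(config.switch_fraction * n))
    n_marker = int(round(config.marker_fraction * n))
    planted = rng.choice(n, size=n_switch + n_marker, replace=False)
    switch_idx, marker_idx = planted[:n_switch], planted[n_switch:]
    is_switch = np.zeros(n, dtype=bool)
    is_switch[switch_idx] = True
    is_marker = np.zeros(n, dtype=bool)
    is_marker[marker_idx] = True
    down = rng.random(n) < config.down_fraction
    sign = np.where(down, -1.0, 1.0)

    means = np.tile(base[:, None], (1, len(TISSUES)))
    # switch cohort: a clean step between PNT and CNT, nothing else
    means[is_switch, 2:] += (sign[is_switch] * config.effect_size)[:, None]
    # tissue markers: one tissue elevated, so every tissue pair is separable
    # (this is what lets replicates cluster by tissue, as real tissues do)
    marker_tissue = rng.integers(0, len(TISSUES), size=n_marker)
    means[marker_idx, marker_tissue] += config.effect_size

    samples = _sample_sheet(config.n_replicates)
    tissue_of_sample = samples["tissue"].map({t: i for i, t in enumerate(TISSUES)}).values

    k = config.probes_per_probeset
    probe_ids = [f"{ps}_p{j + 1:02d}" for ps in ps_ids for j in range(k)]
    layout = pd.Series(np.repeat(ps_ids, k), index=pd.Index(probe_ids, name="probe_id"), name="probeset_id")

    affinity = rng.normal(0.0, 1.0, len(probe_ids))
    probeset_of_probe = np.repeat(np.arange(n), k)
    log2 = means[probeset_of_probe][:, tissue_of_sample] + affinity[:, None]
    if not zero_noise and config.noise_sd > 0:
        log2 = log2 + rng.normal(0.0, config.noise_sd, log2.shape)

    intensities = pd.DataFrame(
        np.exp2(log2), index=pd.Index(probe_ids, name="probe_id"), columns=samples.index
    )

    marker_tissue_col = np.full(n, "", dtype=object)
    marker_tissue_col[marker_idx] = [TISSUES[t] for t in marker_tissue]
    truth_df = pd.DataFrame(
        {
            "is_switch": is_switch,
            "direction": np.where(is_switch, np.where(down, "down", "up"), ""),
            "is_marker": is_marker,
            "marker_tissue": marker_tissue_col,
            **{f"mean_{t}": means[:, i] for i, t in enumerate(TISSUES)},
        },
        index=pd.Index(ps_ids, name="probeset_id"),
    )
    truth = GroundTruth(probesets=truth_df, cell_cycle=dict(DEFAULT_CELL_CYCLE))
    return ProbeIntensityMatrix(intensities, layout, samples), truth


def simulate_edu_counts(
    T_true: float,
    S_true: float,
    exposure_times=(1.0, 4.0),
    n_sections: int = 5,
    cells_per_section: int = 200,
    seed: int | None = 0,
    n_embryos: int = 5,
    zero_noise: bool = False,
    region: str = "SZ",
    mitotic_index_true: float | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-section EdU+ counts under cumulative labeling L(t) = (S + t)/T.

    Counts are Binomial(cells_per_section, L(t)) per section; in zero-noise
    mode the exact expected (possibly fractional) count is emitted so pooled
    labeled fractions are exact, which makes the estimator round-trip
    analytic.
    """
    if not 0 < S_true < T_true:
        raise ValueError(f"need 0 < S < T, got S={S_true}, T={T_true}")
    for t in exposure_times:
        frac = (S_true + t) / T_true
        if t <= 0:
            raise ValueError("exposure times must be positive")
        if frac >= 1:
            raise ValueError(
                f"labeled fraction (S+t)/T = {frac:.3f} >= 1 at t={t}; "
                "require t < T - S for cumulative labeling"
            )
    rng = np.random.default_rng(seed) if rng is None else rng
    rows = []
    for t in exposure_times:
        frac = (S_true + t) / T_true
        for embryo in range(1, n_embryos + 1):
            for section in range(1, n_sections + 1):
                if zero_noise:
                    edu = frac * cells_per_section
                else:
                    edu = int(rng.binomial(cells_per_section, frac))
                row = {
                    "region": region,
                    "embryo": embryo,
                    "section": section,
                    "exposure_h": t,
                    "edu_pos": edu,
                    "total": cells_per_section,
                }
                if mitotic_index_true is not None:
                    if zero_noise:
                        row["ph3_pos"] = mitotic_index_true * cells_per_section
                    else:
                        row["ph3_pos"] = int(rng.binomial(cells_per_section, mitotic_index_true))
                rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class AnnotationBundle:
    """Annotation-layer outputs: vendor annotation with gaps, EST chains,
    ortholog table with ambiguity, toy gene orders, term sets, CASI list."""

    annotation: pd.DataFrame  # probeset_id, gene_id (may be NA), est_ids
    est_to_gene: pd.DataFrame  # est_id, gene_id
    orthologs: pd.DataFrame  # gene_A, gene_B candidate pairs
    orders_a: dict[str, list[str]]  # species A: chrom → ordered genes
    orders_b: dict[str, list[str]]
    similarity_hits: pd.DataFrame  # probeset_id, protein_id, gene_id, identity, length, evalue
    terms: dict[str, set[str]]
    casi_genes: list[str]


def simulate_annotations_and_orthologs(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    truth: GroundTruth | None = None,
    one_to_one_only: bool = False,
    decoy_shared_neighbours: int = 0,
    n_terms: int = 15,
    n_enriched_terms: int = 3,
) -> tuple[AnnotationBundle, GroundTruth]:
    """Generate annotation with planted gaps plus an ortholog/synteny layer.

    A fraction ``annotation_gap`` of probe-sets lack a vendor gene id; enough
    of those carry EST chains to their true gene that chaining closes the gap
    to ``residual_gap``.  The ortholog table mixes 1:1 rows with 1:many and
    many:many blocks whose true member shares ordered neighbours with the
    source gene on toy chromosomes while decoys share
    ``decoy_shared_neighbours`` (0 ⇒ strictly dominated decoys).
    """
    rng = config.rng() if rng is None else rng
    truth = truth if truth is not None else GroundTruth()
    n = config.n_probesets
    ps_ids = _probeset_ids(n)

    # True probe-set → gene map; a small tail of probe-sets shares a gene with
    # the previous one so gene-level deduplication is exercised.
    gene_idx = np.arange(n)
    dup = rng.random(n) < 0.05
    dup[0] = False
    for i in np.where(dup)[0]:
        gene_idx[i] = gene_idx[i - 1]
    genes = np.array([f"GGA{i:05d}" for i in gene_idx])
    gene_map = pd.Series(genes, index=pd.Index(ps_ids, name="probeset_id"), name="gene_id")

    # Vendor annotation gaps; EST chains rescue enough to hit residual_gap.
    n_gap = int(round(config.annotation_gap * n))
    n_rescue = int(round((config.annotation_gap - config.residual_gap) * n))
    gap_idx = rng.choice(n, size=n_gap, replace=False)
    rescued = set(gap_idx[:n_rescue])
    gap_set = set(gap_idx)

    est_rows = []
    ann_rows = []
    est_counter = 0
    for i, ps in enumerate(ps_ids):
        if i not in gap_set:
            ann_rows.append({"probeset_id": ps, "gene_id": genes[i], "est_ids": ""})
            continue
        n_est = int(rng.integers(2, 4))
        ests = [f"EST{est_counter + j:06d}" for j in range(n_est)]
        est_counter += n_est
        ann_rows.append({"probeset_id": ps, "gene_id": "", "est_ids": ",".join(ests)})
        if i in rescued:
            for e in ests:
                est_rows.append({"est_id": e, "gene_id": genes[i]})
    annotation = pd.DataFrame(ann_rows)
    est_to_gene = pd.DataFrame(est_rows, columns=["est_id", "gene_id"])

    # Ortholog layer over the unique species-A genes, in chromosomal order.
    genes_a = [f"GGA{i:05d}" for i in sorted(set(gene_idx))]
    n_genes = len(genes_a)
    true_b = [f"HSA{i:05d}" for i in range(n_genes)]
    rel = rng.random(n_genes)
    if one_to_one_only:
        rel[:] = 0.0
    rows = []
    truth_pairs = []
    decoys: list[str] = []
    i = 0
    while i < n_genes:
        a, b = genes_a[i], true_b[i]
        if rel[i] < 0.8 or i == n_genes - 1:
            rows.append({"gene_A": a, "gene_B": b})
            truth_pairs.append({"gene_A": a, "gene_B": b, "relation": "1:1"})
            i += 1
        elif rel[i] < 0.9:
            decoy = f"HSX{len(decoys):05d}"
            decoys.append(decoy)
            rows.append({"gene_A": a, "gene_B": b})
            rows.append({"gene_A": a, "gene_B": decoy})
            truth_pairs.append({"gene_A": a, "gene_B": b, "relation": "1:many"})
            i += 1
        else:
            a2, b2 = genes_a[i + 1], true_b[i + 1]
            for ga in (a, a2):
                for gb in (b, b2):
                    rows.append({"gene_A": ga, "gene_B": gb})
            truth_pairs.append({"gene_A": a, "gene_B": b, "relation": "many:many"})
            truth_pairs.append({"gene_A": a2, "gene_B": b2, "relation": "many:many"})
            i += 2
    orthologs = pd.DataFrame(rows)
    truth.ortholog_truth = pd.DataFrame(truth_pairs)
    truth.gene_map = gene_map

    # Toy chromosomes: conserved gene order between species; decoys live on a
    # separate chromosome (or interleaved when decoy_shared_neighbours > 0).
    per_chrom = 50
    orders_a = {
        f"chrA{c + 1}": genes_a[c * per_chrom : (c + 1) * per_chrom]
        for c in range((n_genes + per_chrom - 1) // per_chrom)
    }
    orders_b = {
        f"chrB{c + 1}": true_b[c * per_chrom : (c + 1) * per_chrom]
        for c in range((n_genes + per_chrom - 1) // per_chrom)
    }
    if decoys:
        if decoy_shared_neighbours == 0:
            orders_b["chrB_decoy"] = decoys
        else:
            # place each decoy near its rival so it shares some neighbours
            for d in decoys:
                key = next(iter(orders_b))
                orders_b[key] = orders_b[key] + [d]

    # Similarity hits close a handful of the never-rescued gap probe-sets.
    unrescued = [i for i in gap_idx[n_rescue:]][:5]
    hit_rows = []
    for j, i in enumerate(unrescued):
        hit_rows.append(
            {
                "probeset_id": ps_ids[i],
                "protein_id": f"UP{j:05d}",
                "gene_id": genes[i],
                "identity": float(rng.uniform(92, 99)),
                "length": int(rng.integers(80, 200)),
                "evalue": 1e-30,
            }
        )
    similarity_hits = pd.DataFrame(
        hit_rows, columns=["probeset_id", "protein_id", "gene_id", "identity", "length", "evalue"]
    )

    # Term sets: a few enriched in the planted switch cohort, rest background.
    all_genes = sorted(set(genes))
    if truth.probesets is not None:
        switch_ps = truth.probesets.index[truth.probesets["is_switch"]]
        switch_genes = sorted(set(gene_map.loc[switch_ps]))
        planted = truth.probesets["is_switch"] | truth.probesets.get("is_marker", False)
        planted_genes = set(gene_map.loc[truth.probesets.index[planted]])
    else:
        switch_genes = []
        planted_genes = set()
    terms: dict[str, set[str]] = {}
    enriched = []
    for ti in range(n_terms):
        term_id = f"TERM{ti:04d}"
        size = int(rng.integers(10, 31))
        if ti < n_enriched_terms and len(switch_genes) >= size:
            n_sw = int(round(0.8 * size))
            members = list(rng.choice(switch_genes, size=n_sw, replace=False))
            members += list(rng.choice(all_genes, size=size - n_sw, replace=False))
            enriched.append(term_id)
        else:
            members = list(rng.choice(all_genes, size=min(size, len(all_genes)), replace=False))
        terms[term_id] = set(members)
    truth.enriched_terms = enriched

    non_switch = sorted(set(all_genes) - set(switch_genes) - planted_genes)
    casi = list(rng.choice(non_switch, size=min(20, len(non_switch)), replace=False))

    bundle = AnnotationBundle(
        annotation=annotation,
        est_to_gene=est_to_gene,
        orthologs=orthologs,
        orders_a=orders_a,
        orders_b=orders_b,
        similarity_hits=similarity_hits,
        terms=terms,
        casi_genes=sorted(casi),
    )
    return bundle, truth


def make_toy_gene_models(
    n_genes: int = 30,
    gene_length: int = 9000,
    spacing: int = 15000,
    chrom: str = "chr1",
) -> pd.DataFrame:
    """Evenly spaced toy gene models with alternating strands (true 3' ends)."""
    rows = []
    pos = 10000
    for i in range(n_genes):
        strand = "+" if i % 2 == 0 else "-"
        rows.append(
            {
                "gene_id": f"GGA{i:05d}",
                "chrom": chrom,
                "start": pos,
                "end": pos + gene_length,
                "strand": strand,
            }
        )
        pos += gene_length + spacing
    return pd.DataFrame(rows, columns=io.MODEL_COLUMNS)


def simulate_drs_alignments(
    models: pd.DataFrame | None = None,
    expression: pd.Series | None = None,
    utr_extensions: pd.Series | None = None,
    seed: int | None = 0,
    read_length: int = 50,
    tile_step: int = 25,
    reads_per_unit: float = 5.0,
    max_extension: int = 7000,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate 3'-biased read alignments past truncated gene annotations.

    ``models`` are the TRUE gene models (full 3'UTRs).  The emitted annotated
    models have their 3' end pulled back by the planted extension, while
    reads tile contiguously from inside the gene body to exactly the true 3'
    end — so a coverage walk downstream of the annotated end recovers the
    planted extension exactly.  Returns (annotated models, BED reads, truth).
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    if models is None:
        models = make_toy_gene_models()
    models = models.reset_index(drop=True)
    if expression is None:
        expression = pd.Series(
            np.exp2(rng.normal(5.0, 1.0, len(models))), index=models["gene_id"].values
        )
    if (expression < 0).any():
        raise ValueError("expression must be non-negative")
    if utr_extensions is None:
        ext = np.zeros(len(models), dtype=int)
        n_ext = max(1, len(models) // 3)
        planted = rng.choice(len(models), size=n_ext, replace=False)
        ext[planted] = rng.integers(500, max_extension + 1, size=n_ext)
        ext[planted[0]] = max_extension  # guarantee the maximal case is present
        utr_extensions = pd.Series(ext, index=models["gene_id"].values)
    utr_extensions = utr_extensions.reindex(models["gene_id"].values).fillna(0).astype(int)
    # a truncated annotation must still leave a positive gene body
    lengths = (models["end"] - models["start"]).values
    if (utr_extensions.values >= lengths - 500).any():
        raise ValueError("planted extension leaves no annotated gene body")

    annotated = models.copy()
    read_rows = []
    for i, row in models.iterrows():
        e = int(utr_extensions.iloc[i])
        if row.strand == "+":
            ann_end = row.end - e
            annotated.loc[i, "end"] = ann_end
            body_lo, body_hi = row.start, ann_end
        else:
            ann_start = row.start + e
            annotated.loc[i, "start"] = ann_start
            body_lo, body_hi = ann_start, row.end

        # Read mass is proportional to expression and 3'-biased: it sits in
        # the window running from 1 kb inside the annotated body out to the
        # TRUE 3' end.  For truncated annotations most of it falls past the
        # annotated end, so the gene is undercounted until re-annotation.  A
        # deterministic tile (drawn from the same budget) guarantees coverage
        # is contiguous to exactly the true end, making the planted extension
        # recoverable by a coverage walk.
        bias_window = 1000
        tile_starts = []
        if row.strand == "+":
            tip = ann_end + e  # == true end
            s = tip - read_length
            floor = max(body_lo, ann_end - 300) - read_length
            while s > floor:
                tile_starts.append(s)
                s -= tile_step
            lo = max(body_lo, tip - bias_window - e)
            random_range = (lo, tip - read_length + 1)
        else:
            tip = ann_start - e  # == true start (3' end on minus strand)
            s = tip
            ceil = min(row.end, ann_start + 300)
            while s < ceil:
                tile_starts.append(s)
                s += tile_step
            hi = min(row.end, tip + bias_window + e)
            random_range = (tip, hi - read_length + 1)

        n_total = max(len(tile_starts), int(round(reads_per_unit * expression.iloc[i])))
        n_random = n_total - len(tile_starts)
        starts = list(tile_starts) + list(
            rng.integers(random_range[0], random_range[1], size=n_random)
        )
        for s in starts:
            read_rows.append(
                (row.chrom, int(s), int(s) + read_length, row.gene_id, 0, row.strand)
            )

    reads = pd.DataFrame(read_rows, columns=io.BED_COLUMNS)
    reads = reads.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
    truth = GroundTruth(
        utr_extensions=utr_extensions,
        true_models=models,
        drs_expression=pd.Series(expression.values, index=models["gene_id"].values),
    )
    return annotated, reads, truth


def write_simulation(
    config: SimulationConfig, outdir, zero_noise: bool = False
) -> GroundTruth:
    """Run all generators off one seeded stream and write every pipeline input.

    Emits intensities.tsv, layout.tsv, samples.tsv, annotation.tsv,
    est_to_gene.tsv, orthologs.tsv, geneorder_A.tsv, geneorder_B.tsv,
    hits.tsv, terms.gmt, casi_genes.txt, models.gff3, reads.bed,
    edu_counts.csv and truth.json under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = config.rng()

    pim, truth = simulate_probe_intensities(config, zero_noise=zero_noise, rng=rng)
    pim.intensities.to_csv(outdir / "intensities.tsv", sep="\t")
    pim.layout.reset_index().to_csv(outdir / "layout.tsv", sep="\t", index=False)
    pim.samples.reset_index().to_csv(outdir / "samples.tsv", sep="\t", index=False)

    bundle, truth = simulate_annotations_and_orthologs(config, rng=rng, truth=truth)
    io.write_tsv(bundle.annotation, outdir / "annotation.tsv")
    io.write_tsv(bundle.est_to_gene, outdir / "est_to_gene.tsv")
    io.write_tsv(bundle.orthologs, outdir / "orthologs.tsv")
    for species, orders in (("A", bundle.orders_a), ("B", bundle.orders_b)):
        rows = [
            {"chrom": chrom, "rank": r, "gene_id": g}
            for chrom, glist in orders.items()
            for r, g in enumerate(glist)
        ]
        io.write_tsv(pd.DataFrame(rows), outdir / f"geneorder_{species}.tsv")
    io.write_tsv(bundle.similarity_hits, outdir / "hits.tsv")
    io.write_gmt(bundle.terms, outdir / "terms.gmt")
    io.write_gene_list(bundle.casi_genes, outdir / "casi_genes.txt")

    annotated, reads, drs_truth = simulate_drs_alignments(rng=rng)
    io.write_gff3_models(annotated, outdir / "models.gff3")
    io.write_bed(reads, outdir / "reads.bed")
    truth.utr_extensions = drs_truth.utr_extensions
    truth.true_models = drs_truth.true_models
    truth.drs_expression = drs_truth.drs_expression

    edu_frames = []
    for region, (T, S) in DEFAULT_CELL_CYCLE.items():
        mi = 0.08 * (8.0 / T)  # mitotic index shrinks as the cycle lengthens
        edu_frames.append(
            simulate_edu_counts(
                T, S, zero_noise=zero_noise, region=region, mitotic_index_true=mi, rng=rng
            )
        )
    pd.concat(edu_frames, ignore_index=True).to_csv(outdir / "edu_counts.csv", index=False)
    truth.cell_cycle = dict(DEFAULT_CELL_CYCLE)

    truth.to_json(outdir / "truth.json")
    with open(outdir / "simulation_log.json", "w") as fh:
        json.dump({"config": dataclasses.asdict(config), "zero_noise": zero_noise}, fh, indent=1)
    return truth
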