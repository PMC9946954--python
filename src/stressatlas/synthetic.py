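"""Synthetic stress-atlas generator with a planted regulatory truth.

The generator emulates the statistical structure the downstream analyses
assume: a sparse TF -> target network with activators and repressors,
stress-specific TF activation (disjoint TF blocks per stress by default),
single-stress log2 fold changes obtained by propagating TF activation
through the network, and combined-stress fold changes built additively as

    S_xy = b0 + bx * S_x + by * S_y + noise        (per gene)

where S_x and S_y are the realized single-stress fold-change vectors of the
two stresses in the pair.  Expression values are then sampled around
baseline * 2**log2fc with multiplicative log-normal replicate noise, and
per-contrast differential-expression tables are computed with a Welch
t-test on log2(TPM+1) and Benjamini-Hochberg correction (a deliberately
simple stand-in for a count-based DE model: only the downstream
consolidation logic consumes these tables).

Seeding: one global seed fans out to per-stage child seeds by fixed
offsets — truth +1, log2fc +2, expression +3, annotations +4, orthology +5
(all taken modulo 2**31).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .design import StressDesign, make_design
from .io import AnnotationMap, ExpressionMatrix, ReferenceNetwork

TRUTH_SEED_OFFSET = 1
LOG2FC_SEED_OFFSET = 2
EXPRESSION_SEED_OFFSET = 3
ANNOTATION_SEED_OFFSET = 4
ORTHOLOGY_SEED_OFFSET = 5

#: global-average additivity coefficients used as generator defaults
DEFAULT_ADDITIVITY = (-0.04, 0.61, 0.69)


def _child_rng(seed: int, offset: int) -> np.random.Generator:
    return np.random.default_rng((int(seed) + offset) % 2**31)


@dataclass
class PlantedTruth:
    """Ground truth behind a synthetic atlas."""

    tfs: tuple[str, ...]
    genes: tuple[str, ...]  # non-TF target genes
    #: (tf, gene, coefficient, mode); activators have coefficient > 0
    grn_edges: tuple[tuple[str, str, float, str], ...]
    #: stress letter -> {tf: signed activation level}
    tf_activation: dict[str, dict[str, float]]
    #: combined code -> (b0, bx, by); bx multiplies the first letter's vector
    additivity_params: dict[str, tuple[float, float, float]]
    noise_sd: float
    seed: int
    #: stress letter -> tuple of TFs in its activation block
    tf_blocks: dict[str, tuple[str, ...]] = field(default_factory=dict)

    @property
    def all_genes(self) -> tuple[str, ...]:
        """TFs first, then targets; the row order of every simulated vector."""
        return self.tfs + self.genes

    def coefficient_matrix(self) -> np.ndarray:
        """(n_all_genes x n_tfs) propagation matrix.

        A TF's own expression change equals its activation (identity block);
        a target's change is the sum of its regulators' weighted activations.
        """
        n_tf = len(self.tfs)
        tf_index = {t: i for i, t in enumerate(self.tfs)}
        gene_index = {g: n_tf + i for i, g in enumerate(self.genes)}
        mat = np.zeros((n_tf + len(self.genes), n_tf))
        mat[:n_tf, :n_tf] = np.eye(n_tf)
        for tf, gene, coef, _mode in self.grn_edges:
            mat[gene_index[gene], tf_index[tf]] = coef
        return mat

    def strongest_regulator(self) -> dict[str, str]:
        """Per target, the planted TF with the largest absolute coefficient."""
        best: dict[str, tuple[float, str]] = {}
        for tf, gene, coef, _mode in self.grn_edges:
            key = (abs(coef), tf)
            if gene not in best or key > best[gene]:
                best[gene] = key
        return {g: tf for g, (_c, tf) in best.items()}


def uniform_additivity(
    design: StressDesign, b0: float, bx: float, by: float
) -> dict[str, tuple[float, float, float]]:
    """Same additive coefficients for every combined condition."""
    return {code: (b0, bx, by) for code in design.combined_codes}


def dominance_additivity(
    design: StressDesign, dominance: dict[str, float], b0: float = 0.0
) -> dict[str, tuple[float, float, float]]:
    """Per-combination coefficients from per-stress dominance weights.

    For combined code ``xy`` the first letter's vector gets weight
    ``dominance[x]`` and the second ``dominance[y]``, so a stress carries
    the same weight in every combination it takes part in.
    """
    return {
        code: (b0, dominance[code[0]], dominance[code[1]]) for code in design.combined_codes
    }


def plant_truth(
    design: StressDesign,
    n_genes: int = 2000,
    n_tfs: int = 50,
    edge_density: float = 0.02,
    activator_fraction: float = 0.7,
    additivity_params: dict[str, tuple[float, float, float]] | None = None,
    noise_sd: float = 0.5,
    seed: int = 1,
    block_overlap: float = 0.0,
    activation_range: tuple[float, float] = (2.5, 4.5),
    coefficient_range: tuple[float, float] = (0.5, 1.5),
) -> PlantedTruth:
    """Sample a sparse planted TF -> target network and stress activations.

    Each stress activates its own (disjoint by default) block of TFs with a
    signed level drawn from ``activation_range``; ``block_overlap`` lets a
    fraction of the next stress's block respond too, so dominance structure
    is controllable.  Edges are Bernoulli(``edge_density``) over the
    TF x target bipartite grid; every TF is guaranteed at least one target.
    """
    if n_tfs <= 0:
        raise ValueError("need at least one TF")
    if n_tfs >= n_genes:
        raise ValueError("n_tfs must be smaller than n_genes")
    if not 0 < edge_density <= 1:
        raise ValueError("edge_density must be in (0, 1]")
    if not 0 <= activator_fraction <= 1:
        raise ValueError("activator_fraction must be in [0, 1]")

    rng = _child_rng(seed, TRUTH_SEED_OFFSET)
    # liverwort-style identifiers: TFs on pseudo-chromosome 1, targets on 2,
    # so the case-normalization of annotation files is exercised end to end
    tfs = tuple(f"Mp1g{i:05d}" for i in range(1, n_tfs + 1))
    genes = tuple(f"Mp2g{i:05d}" for i in range(1, n_genes + 1))

    adjacency = rng.random((n_tfs, n_genes)) < edge_density
    for i in range(n_tfs):  # every planted TF regulates >= 1 gene
        if not adjacency[i].any():
            adjacency[i, rng.integers(n_genes)] = True

    lo, hi = coefficient_range
    edges = []
    for i, j in zip(*np.nonzero(adjacency)):
        mode = "activator" if rng.random() < activator_fraction else "repressor"
        coef = float(rng.uniform(lo, hi))
        if mode == "repressor":
            coef = -coef
        edges.append((tfs[i], genes[j], coef, mode))

    # disjoint TF blocks per stress, optional overlap into the next block
    shuffled = list(tfs)
    rng.shuffle(shuffled)
    n_stress = len(design.single_codes)
    bounds = np.linspace(0, n_tfs, n_stress + 1).astype(int)
    blocks = {
        s: tuple(shuffled[bounds[k] : bounds[k + 1]])
        for k, s in enumerate(design.single_codes)
    }
    a_lo, a_hi = activation_range
    activation: dict[str, dict[str, float]] = {}
    for k, s in enumerate(design.single_codes):
        act: dict[str, float] = {}
        members = list(blocks[s])
        if block_overlap > 0:
            nxt = blocks[design.single_codes[(k + 1) % n_stress]]
            n_shared = int(round(block_overlap * len(nxt)))
            members.extend(nxt[:n_shared])
        for tf in members:
            level = float(rng.uniform(a_lo, a_hi))
            if rng.random() < 0.5:
                level = -level
            act[tf] = level
        activation[s] = act

    if additivity_params is None:
        additivity_params = uniform_additivity(design, *DEFAULT_ADDITIVITY)

    return PlantedTruth(
        tfs=tfs,
        genes=genes,
        grn_edges=tuple(edges),
        tf_activation=activation,
        additivity_params=dict(additivity_params),
        noise_sd=float(noise_sd),
        seed=int(seed),
        tf_blocks=blocks,
    )


def simulate_log2fc(
    truth: PlantedTruth, design: StressDesign, seed: int | None = None
) -> dict[str, np.ndarray]:
    """Per-condition log2 fold-change vectors over ``truth.all_genes``.

    Single stresses propagate TF activation through the planted network and
    add Normal(0, noise_sd) noise; a combined condition ``xy`` is the
    additive mix of the two *realized* single-stress vectors plus fresh
    noise, so the additive relation holds exactly at noise_sd = 0.
    """
    for code in design.combined_codes:
        if code not in truth.additivity_params:
            raise ValueError(f"no additivity parameters for combined condition {code!r}")
    rng = _child_rng(truth.seed if seed is None else seed, LOG2FC_SEED_OFFSET)
    mat = truth.coefficient_matrix()
    n_all = mat.shape[0]
    tf_index = {t: i for i, t in enumerate(truth.tfs)}

    out: dict[str, np.ndarray] = {}
    for s in design.single_codes:
        act = np.zeros(len(truth.tfs))
        for tf, level in truth.tf_activation.get(s, {}).items():
            act[tf_index[tf]] = level
        noise = rng.normal(0.0, truth.noise_sd, n_all) if truth.noise_sd > 0 else 0.0
        out[s] = mat @ act + noise
    for code in design.combined_codes:
        x, y = code[0], code[1]
        b0, bx, by = truth.additivity_params[code]
        noise = rng.normal(0.0, truth.noise_sd, n_all) if truth.noise_sd > 0 else 0.0
        out[code] = b0 + bx * out[x] + by * out[y] + noise
    return out


def _welch_de_table(
    log_cond: np.ndarray, log_ctrl: np.ndarray, genes: tuple[str, ...]
) -> pd.DataFrame:
    """Per-gene Welch t-test on log2(TPM+1) replicate values, BH across genes."""
    lfc = log_cond.mean(axis=1) - log_ctrl.mean(axis=1)
    tres = stats.ttest_ind(log_cond, log_ctrl, axis=1, equal_var=False)
    pvals = np.nan_to_num(tres.pvalue, nan=1.0)
    padj = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame({"gene": genes, "log2fc": lfc, "pvalue": pvals, "padj": padj})


def simulate_expression(
    truth: PlantedTruth,
    design: StressDesign,
    log2fc: dict[str, np.ndarray],
    baseline_mean: float = 100.0,
    dispersion: float = 0.25,
    seed: int | None = None,
    baseline_log2_sd: float = 1.5,
) -> tuple[ExpressionMatrix, dict[tuple[str, str], pd.DataFrame]]:
    """Expression matrix plus per-contrast DE tables (vs ctrl_F and ctrl_L).

    Per-gene baselines are log-normal around ``baseline_mean``; a condition's
    mean is baseline * 2**log2fc and replicates get multiplicative
    2**Normal(0, dispersion) noise.  Both control batches are drawn from the
    same baseline distribution.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    rng = _child_rng(truth.seed if seed is None else seed, EXPRESSION_SEED_OFFSET)
    genes = truth.all_genes
    n_all = len(genes)
    baseline = baseline_mean * 2.0 ** rng.normal(0.0, baseline_log2_sd, n_all)

    cols: dict[str, np.ndarray] = {}
    meta_rows = []
    for sample in design.samples:
        cond_lfc = log2fc.get(sample.condition, np.zeros(n_all))
        mean = baseline * 2.0**cond_lfc
        vals = mean * 2.0 ** rng.normal(0.0, dispersion, n_all)
        cols[sample.sample_id] = vals
        meta_rows.append(
            {
                "sample": sample.sample_id,
                "condition": sample.condition,
                "replicate": sample.replicate,
                "batch": sample.batch,
            }
        )
    values = pd.DataFrame(cols, index=list(genes))
    matrix = ExpressionMatrix(values=values, metadata=pd.DataFrame(meta_rows))

    log_values = np.log2(values.to_numpy() + 1.0)
    col_index = {s: i for i, s in enumerate(values.columns)}

    def _cols(condition: str) -> np.ndarray:
        ids = matrix.samples_for([condition])
        return log_values[:, [col_index[s] for s in ids]]

    de_tables: dict[tuple[str, str], pd.DataFrame] = {}
    for batch, ctrl in (("F", "ctrl_F"), ("L", "ctrl_L")):
        log_ctrl = _cols(ctrl)
        for cond in design.stress_conditions:
            de_tables[(cond, batch)] = _welch_de_table(_cols(cond), log_ctrl, genes)
    return matrix, de_tables


# ---------------------------------------------------------------------------
# planted annotations (functional bins, TF families, orthology)


def plant_annotations(
    truth: PlantedTruth, n_bins: int = 20, seed: int | None = None
) -> AnnotationMap:
    """Random functional-bin assignment plus TF-family labels.

    Every gene gets one second-level bin code ("1.1", "1.2", ...); TFs get a
    synthetic family label.  Bin membership is independent of the planted
    network — module-aligned bins for recovery checks come from
    :func:`plant_module_bins`.
    """
    rng = _child_rng(truth.seed if seed is None else seed, ANNOTATION_SEED_OFFSET)
    codes = [f"{1 + k // 10}.{1 + k % 10}" for k in range(n_bins)]
    ann = AnnotationMap()
    for g in truth.all_genes:
        ann.gene_to_bins[g] = {codes[int(rng.integers(n_bins))]}
    for i, tf in enumerate(truth.tfs):
        ann.gene_to_tf_family[tf] = f"FAM{1 + i % 8}"
    return ann


def plant_module_bins(truth: PlantedTruth) -> AnnotationMap:
    """Bins aligned with the planted regulatory modules.

    Each target gene is binned by its strongest planted regulator (bin code
    ``<tf index>.1``), so a perfect inference should link each TF to its own
    bin.  TFs keep their family labels; genes without a regulator share a
    catch-all bin "0.1".
    """
    strongest = truth.strongest_regulator()
    tf_code = {tf: f"{i + 1}.1" for i, tf in enumerate(truth.tfs)}
    ann = AnnotationMap()
    for g in truth.genes:
        ann.gene_to_bins[g] = {tf_code[strongest[g]]} if g in strongest else {"0.1"}
    for i, tf in enumerate(truth.tfs):
        ann.gene_to_tf_family[tf] = f"FAM{1 + i % 8}"
    return ann


def plant_orthology(
    truth: PlantedTruth,
    genes_per_family: int = 2,
    seed: int | None = None,
) -> tuple[AnnotationMap, AnnotationMap]:
    """Family maps for the simulated species and a pseudo second species.

    Genes are grouped into orthogroups of ``genes_per_family`` consecutive
    members (TFs into their own orthogroups); the second species carries one
    gene per family named after it, so every family is shared.
    """
    fam_a = AnnotationMap()
    fams: list[str] = []
    for i, tf in enumerate(truth.tfs):
        fam = f"OGTF{i:04d}"
        fam_a.gene_to_family[tf] = fam
        fams.append(fam)
    for j, g in enumerate(truth.genes):
        fam = f"OG{j // genes_per_family:05d}"
        fam_a.gene_to_family[g] = fam
        if fam not in fams or fams[-1] != fam:
            fams.append(fam)
    fam_b = AnnotationMap()
    for fam in dict.fromkeys(fams):
        fam_b.gene_to_family[f"At_{fam}"] = fam
    return fam_a, fam_b


def plant_reference_network(
    truth: PlantedTruth,
    fam_a: AnnotationMap,
    fam_b: AnnotationMap,
    true_fraction: float = 0.5,
    n_noise_edges: int = 0,
    seed: int | None = None,
) -> ReferenceNetwork:
    """A curated-network stand-in in the second species' gene ids.

    A ``true_fraction`` subsample of the planted edges is translated through
    the orthogroup maps, optionally diluted with random regulator/target
    pairings, mimicking an independently curated reference.
    """
    rng = _child_rng(truth.seed if seed is None else seed, ORTHOLOGY_SEED_OFFSET)
    b_gene_of_family = {fam: g for g, fam in fam_b.gene_to_family.items()}
    edges = set()
    for tf, gene, _coef, _mode in truth.grn_edges:
        if rng.random() >= true_fraction:
            continue
        rf, tf_fam = fam_a.gene_to_family.get(gene), fam_a.gene_to_family.get(tf)
        if rf is None or tf_fam is None:
            continue
        edges.add((b_gene_of_family[tf_fam], b_gene_of_family[rf]))
    if n_noise_edges:
        b_tfs = sorted(b_gene_of_family[f] for f in fam_b.gene_to_family.values() if f.startswith("OGTF"))
        b_genes = sorted(b_gene_of_family[f] for f in fam_b.gene_to_family.values() if not f.startswith("OGTF"))
        for _ in range(n_noise_edges):
            edges.add(
                (
                    b_tfs[int(rng.integers(len(b_tfs)))],
                    b_genes[int(rng.integers(len(b_genes)))],
                )
            )
    return ReferenceNetwork(edges=frozenset(edges), species="pseudo")


def generate_bundle(
    seed: int = 1,
    n_replicates: int = 3,
    n_genes: int = 2000,
    n_tfs: int = 50,
    edge_density: float = 0.02,
    noise_sd: float = 0.5,
    dispersion: float = 0.25,
    additivity_params: dict[str, tuple[float, float, float]] | None = None,
    **plant_kwargs,
):
    """One-call synthetic atlas: design, truth, log2fc, expression, DE tables."""
    design = make_design(n_replicates=n_replicates, seed=seed)
    truth = plant_truth(
        design,
        n_genes=n_genes,
        n_tfs=n_tfs,
        edge_density=edge_density,
        additivity_params=additivity_params,
        noise_sd=noise_sd,
        seed=seed,
        **plant_kwargs,
    )
    lfc = simulate_log2fc(truth, design)
    matrix, de_tables = simulate_expression(truth, design, lfc, dispersion=dispersion)
    return design, truth, lfc, matrix, de_tables
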