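"""Ground-truthed synthetic scRNA-seq datasets for the glioma NGS pipeline.

The generator emulates the statistical structure every downstream stage
assumes, with full knowledge of the planted truth:

* several normal cell types, each carrying a set of near-exclusive marker
  genes (high on-state mean, near-zero off-state mean, as real cell-type
  markers behave);
* a malignant population carrying chromosome-arm expression shifts
  (copy-number gains/losses acting multiplicatively on the mean);
* a neuron-glioma-synapse (NGS) gene program elevated in a subset of the
  malignant cells;
* lncRNAs whose expression correlates with their target NGS genes through a
  shared log-normal latent factor, with the loading calibrated analytically
  so the *realized* count-level Pearson correlation matches the configured
  strength despite negative-binomial sampling noise;
* lncRNA and promoter sequences with planted triplex-compatible
  homopurine/homopyrimidine tracts for the binding-site finder.

Counts are negative binomial per gene with a shared dispersion. Same seed,
same config => bit-identical output.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
import pandas as pd

from .matrix import PROTOCOL_TPM, PROTOCOL_UMI, ExpressionMatrix, normalize_protocol

#: NGS genes named in the literature; the remainder of the default 34-gene
#: signature is filled with synthetic ids (NGS12..NGS34).
NGS_CORE_GENES = [
    "PTPRS", "MAP2", "CADM1", "NLGN3", "GABBR1", "NRCAM",
    "GLRB", "GRIA4", "GRIK3", "INA", "GRIA2",
]

_MITO_GENES = [
    "MT-ND1", "MT-ND2", "MT-ND3", "MT-ND4", "MT-CO1", "MT-CO2",
    "MT-CO3", "MT-ATP6", "MT-ATP8", "MT-CYB",
]

_DEF_CELL_TYPES = [
    ("oligodendrocyte", 20, 60.0),
    ("astrocyte", 20, 60.0),
    ("macrophage", 20, 60.0),
]

_DEF_EDGES = [
    ("LNC01", ["MAP2"], 0.6),
    ("LNC02", ["NRCAM"], 0.6),
    ("LNC03", ["GRIA2"], 0.6),
]

PYRIMIDINES = "TC"
_PUR_FOR_PYR = {"T": "A", "C": "G"}  # parallel-motif triplex code


@dataclasses.dataclass
class SimConfig:
    """Study conditions of the simulated glioma dataset.

    ``cell_types`` entries are ``(name, n_markers, marker_fold)``;
    ``cnv_events`` entries are ``(chromosome, "gain"|"loss", log2_shift,
    n_genes_affected)``; ``lnc_target_map`` entries are ``(lncRNA, target
    NGS genes, correlation strength)``. ``tract_map`` lists the
    (lncRNA, gene) pairs that receive a planted triplex tract in the gene's
    promoter; by default every configured correlation pair does. Listing a
    pair in only one of the two maps produces correlation-only or
    binding-only decoys.
    """

    n_genes: int = 1600
    n_chromosomes: int = 8
    n_cells_per_type: int = 200
    cell_types: list = dataclasses.field(default_factory=lambda: list(_DEF_CELL_TYPES))
    n_malignant: int = 500
    cnv_events: list = dataclasses.field(
        default_factory=lambda: [("chr7", "gain", 0.5, 200)]
    )
    ngs_signature_size: int = 34
    ngs_positive_fraction: float = 0.5
    ngs_fold: float = 2.0
    n_lncRNAs: int = 10
    lnc_target_map: list = dataclasses.field(default_factory=lambda: list(_DEF_EDGES))
    tract_map: list | None = None
    baseline_mean: float = 5.0
    dispersion: float = 10.0
    latent_sd: float = 1.0
    marker_off_mean: float = 0.05
    protocol: str = PROTOCOL_TPM
    seed: int = 0
    # sequence generation
    lnc_length: int = 600
    promoter_length: int = 5000
    tract_length: int = 160
    allow_role_overlap: bool = False

    def __post_init__(self) -> None:
        self.protocol = normalize_protocol(self.protocol)
        if not 0.0 <= self.ngs_positive_fraction <= 1.0:
            raise ValueError("ngs_positive_fraction must be in [0, 1]")
        for name, value in [
            ("n_genes", self.n_genes),
            ("n_chromosomes", self.n_chromosomes),
            ("n_cells_per_type", self.n_cells_per_type),
            ("n_malignant", self.n_malignant),
            ("ngs_signature_size", self.ngs_signature_size),
        ]:
            if value <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tract_map is None:
            self.tract_map = [
                (lnc, gene)
                for lnc, targets, _ in self.lnc_target_map
                for gene in targets
            ]

    # -- derived gene universe ------------------------------------------
    @property
    def ngs_genes(self) -> list[str]:
        n = self.ngs_signature_size
        names = NGS_CORE_GENES[:n]
        names += [f"NGS{i:02d}" for i in range(len(names) + 1, n + 1)]
        return names

    @property
    def lnc_genes(self) -> list[str]:
        return [f"LNC{i:02d}" for i in range(1, self.n_lncRNAs + 1)]

    @property
    def marker_genes(self) -> dict[str, list[str]]:
        out = {}
        for name, n_markers, _fold in self.cell_types:
            if n_markers <= 0:
                raise ValueError(f"cell type {name!r} must have >= 1 marker gene")
            out[name] = [f"{name[:3].upper()}MK{i:02d}" for i in range(1, n_markers + 1)]
        return out

    def validate_roles(self) -> None:
        """Check planted ids exist and no gene holds two roles."""
        marker_set = {g for gs in self.marker_genes.values() for g in gs}
        ngs_set = set(self.ngs_genes)
        lnc_set = set(self.lnc_genes)
        for lnc, targets, strength in self.lnc_target_map:
            if lnc not in lnc_set:
                raise ValueError(f"unknown lncRNA {lnc!r} in lnc_target_map")
            if not -1.0 <= strength <= 1.0:
                raise ValueError(f"correlation strength {strength} outside [-1, 1]")
            for gene in targets:
                if gene in ngs_set:
                    continue
                if gene in marker_set or gene in lnc_set:
                    if not self.allow_role_overlap:
                        raise ValueError(
                            f"gene {gene!r} already holds another role; "
                            "set allow_role_overlap=True to permit this"
                        )
                else:
                    raise ValueError(f"lncRNA target {gene!r} is not an NGS gene")
        valid_tract_genes = ngs_set | marker_set | lnc_set
        for lnc, gene in self.tract_map:
            if lnc not in lnc_set:
                raise ValueError(f"unknown lncRNA {lnc!r} in tract_map")
            if gene not in valid_tract_genes:
                raise ValueError(f"unknown tract_map gene {gene!r}")


@dataclasses.dataclass
class SimTruth:
    """Planted ground truth accompanying a simulated dataset."""

    cell_table: pd.DataFrame          # true_type, malignant, ngs_positive
    gene_roles: pd.DataFrame          # role, marker_type
    gene_annotation: pd.DataFrame     # gene, chrom, start, end, strand
    cnv_segments: list
    edges: list                       # (lncRNA, target, strength)
    tract_edges: list                 # (lncRNA, gene)
    counts: pd.DataFrame              # raw NB counts, genes x cells
    signature: list

    def validate(self) -> None:
        if self.cell_table.index.has_duplicates or self.gene_roles.index.has_duplicates:
            raise ValueError("truth labels must cover each cell/gene exactly once")


# -- helpers -------------------------------------------------------------

def _latent_loadings(base_lnc, bases_tgt, strengths, sigma, theta):
    """Per-gene loadings on the shared latent factor.

    The realized count correlation between two genes with log-normal latent
    multipliers (log-sd sigma, log-space correlation a_l*a_t) and NB noise is

        r = (exp(sigma^2 a_l a_t) - 1) / sqrt(d_l * d_t),
        d_g = (e^{sigma^2}-1) + e^{sigma^2}/theta + 1/b_g.

    Inverting for the configured r gives the loading product; the lncRNA
    takes the largest required loading and each target the remainder.
    """
    e = math.exp(sigma**2)

    def d(b):
        return (e - 1.0) + e / theta + 1.0 / b

    products = []
    for b_t, r in zip(bases_tgt, strengths):
        c = math.log(1.0 + r * math.sqrt(d(base_lnc) * d(b_t))) / sigma**2
        if c > 1.0:
            warnings.warn(
                f"requested correlation {r} exceeds the attainable maximum "
                "for these expression levels; clamping latent loading"
            )
            c = 1.0
        products.append(c)
    a_l = min(1.0, math.sqrt(max(products))) if products else 0.0
    a_t = [min(1.0, c / a_l) if a_l > 0 else 0.0 for c in products]
    return a_l, a_t


def _random_seq(rng, length: int) -> np.ndarray:
    return rng.choice(list("ACGT"), size=length)


# -- main operations ------------------------------------------------------

def generate_expression(config: SimConfig) -> tuple[ExpressionMatrix, SimTruth]:
    """Draw a genes x cells matrix with the configured planted structure."""
    config.validate_roles()
    rng = np.random.default_rng(config.seed)

    marker_map = config.marker_genes
    ngs_genes = config.ngs_genes
    lnc_genes = config.lnc_genes
    special = (
        [g for gs in marker_map.values() for g in gs] + ngs_genes + lnc_genes
    )
    if len(set(special)) != len(special) and not config.allow_role_overlap:
        dupes = sorted({g for g in special if special.count(g) > 1})
        raise ValueError(f"genes assigned to more than one role: {dupes}")
    n_filler = config.n_genes - len(special) - len(_MITO_GENES)
    if n_filler < 0:
        raise ValueError("n_genes too small for the configured roles")
    filler = [f"G{i:04d}" for i in range(1, n_filler + 1)]

    # genomic layout: filler spread over autosomal chromosomes so CNV events
    # hit passenger genes; role genes parked on the last chromosome; MT apart
    chroms = [f"chr{i}" for i in range(1, config.n_chromosomes + 1)]
    per_chrom = max(1, len(filler) // (len(chroms) - 1))
    records = []
    idx = 0
    for chrom in chroms[:-1]:
        block = filler[idx: idx + per_chrom]
        idx += per_chrom
        for k, gene in enumerate(block):
            records.append((gene, chrom, 10_000 * (k + 1)))
    leftover = filler[idx:]
    for k, gene in enumerate(leftover + special):
        records.append((gene, chroms[-1], 10_000 * (k + 1)))
    for k, gene in enumerate(_MITO_GENES):
        records.append((gene, "chrM", 1_000 * (k + 1)))
    annotation = pd.DataFrame(records, columns=["gene", "chrom", "start"])
    annotation["end"] = annotation["start"] + 1_000
    annotation["strand"] = np.where(np.arange(len(annotation)) % 2 == 0, "+", "-")
    annotation = annotation.set_index("gene", drop=False)

    genes = annotation.index.to_list()
    gene_pos = {g: i for i, g in enumerate(genes)}

    # baseline means
    base = rng.lognormal(mean=math.log(config.baseline_mean), sigma=1.0, size=len(genes))
    for gs in marker_map.values():
        for g in gs:
            base[gene_pos[g]] = config.marker_off_mean
    for g in ngs_genes:
        base[gene_pos[g]] = rng.uniform(10.0, 50.0)
    for g in lnc_genes:
        base[gene_pos[g]] = rng.uniform(20.0, 40.0)
    for g in _MITO_GENES:
        base[gene_pos[g]] = rng.uniform(10.0, 30.0)

    # cells
    cell_ids, cell_type = [], []
    for name, _n_markers, _fold in config.cell_types:
        for i in range(config.n_cells_per_type):
            cell_ids.append(f"{name}_{i:04d}")
            cell_type.append(name)
    for i in range(config.n_malignant):
        cell_ids.append(f"malig_{i:04d}")
        cell_type.append("malignant")
    cell_type = np.array(cell_type)
    n_cells = len(cell_ids)
    malignant = cell_type == "malignant"

    n_pos = int(round(config.ngs_positive_fraction * config.n_malignant))
    malig_idx = np.flatnonzero(malignant)
    ngs_pos_idx = rng.choice(malig_idx, size=n_pos, replace=False)
    ngs_positive = np.zeros(n_cells, dtype=bool)
    ngs_positive[ngs_pos_idx] = True

    # mean matrix with planted programs
    mu = np.tile(base[:, None], (1, n_cells))
    for name, _n, fold in config.cell_types:
        cols = cell_type == name
        for g in marker_map[name]:
            mu[gene_pos[g], cols] *= fold

    cnv_segments = []
    for chrom, direction, shift, n_aff in config.cnv_events:
        if direction not in ("gain", "loss"):
            raise ValueError(f"cnv direction must be 'gain' or 'loss', got {direction!r}")
        chrom_genes = annotation.index[annotation["chrom"] == chrom].to_list()
        if len(chrom_genes) < n_aff:
            raise ValueError(
                f"{chrom} has only {len(chrom_genes)} genes (< {n_aff} requested)"
            )
        affected = chrom_genes[:n_aff]
        factor = 2.0 ** (shift if direction == "gain" else -shift)
        rows = [gene_pos[g] for g in affected]
        mu[np.ix_(rows, malignant)] *= factor
        cnv_segments.append(
            {"chrom": chrom, "direction": direction, "log2_shift": shift,
             "genes": affected}
        )

    for g in ngs_genes:
        mu[gene_pos[g], ngs_positive] *= config.ngs_fold

    sigma = config.latent_sd
    for lnc, targets, strength in config.lnc_target_map:
        a_l, a_ts = _latent_loadings(
            base[gene_pos[lnc]],
            [base[gene_pos[t]] for t in targets],
            [strength] * len(targets),
            sigma,
            config.dispersion,
        )
        z = rng.standard_normal(n_cells)
        for g, a in [(lnc, a_l)] + list(zip(targets, a_ts)):
            f = a * z + math.sqrt(max(0.0, 1.0 - a * a)) * rng.standard_normal(n_cells)
            mu[gene_pos[g]] *= np.exp(sigma * f - sigma**2 / 2.0)

    theta = config.dispersion
    p = theta / (theta + mu)
    counts = rng.negative_binomial(theta, p).astype(float)
    counts_df = pd.DataFrame(counts, index=genes, columns=cell_ids)

    if config.protocol == PROTOCOL_TPM:
        totals = counts_df.sum(axis=0)
        totals[totals == 0] = 1.0
        values = counts_df / totals * 1e6
    else:
        values = counts_df.copy()
    matrix = ExpressionMatrix(values, config.protocol)

    roles = pd.DataFrame({"role": "filler", "marker_type": ""}, index=pd.Index(genes, name="gene"))
    for name, gs in marker_map.items():
        roles.loc[gs, ["role", "marker_type"]] = ["marker", name]
    roles.loc[ngs_genes, "role"] = "ngs"
    roles.loc[lnc_genes, "role"] = "lncRNA"
    roles.loc[_MITO_GENES, "role"] = "mito"

    truth = SimTruth(
        cell_table=pd.DataFrame(
            {"true_type": cell_type, "malignant": malignant, "ngs_positive": ngs_positive},
            index=pd.Index(cell_ids, name="cell"),
        ),
        gene_roles=roles,
        gene_annotation=annotation,
        cnv_segments=cnv_segments,
        edges=[tuple(e) for e in config.lnc_target_map],
        tract_edges=[tuple(t) for t in config.tract_map],
        counts=counts_df,
        signature=ngs_genes,
    )
    truth.validate()
    return matrix, truth


def generate_marker_db(config: SimConfig) -> dict[str, list[str]]:
    """Cell-type -> marker gene list, exactly the planted markers."""
    return config.marker_genes


def generate_sequences(
    config: SimConfig, seed: int | None = None
) -> tuple[dict[str, str], dict[str, str], pd.DataFrame]:
    """lncRNA sequences, promoter sequences, and planted-target BED.

    Each (lncRNA, gene) pair in ``tract_map`` yields a homopyrimidine tract
    in the lncRNA and the matched homopurine tract (parallel triplex code:
    U.A and C.G) in the gene's promoter. Promoters are generated for every
    NGS gene; promoters of genes without a planted pair are random sequence.
    The BED frame records planted DNA intervals (0-based half-open).
    """
    if not config.lnc_target_map and not config.tract_map:
        raise ValueError("no lncRNA->gene edges configured")
    if config.tract_length > config.promoter_length:
        raise ValueError(
            f"tract_length {config.tract_length} exceeds promoter window "
            f"{config.promoter_length}"
        )
    if config.tract_length > config.lnc_length:
        raise ValueError("tract_length exceeds lncRNA length")
    rng = np.random.default_rng(config.seed if seed is None else seed)

    lnc_seqs: dict[str, np.ndarray] = {
        lnc: _random_seq(rng, config.lnc_length) for lnc in config.lnc_genes
    }
    prom_genes = list(dict.fromkeys(config.ngs_genes + [g for _l, g in config.tract_map]))
    prom_seqs: dict[str, np.ndarray] = {
        g: _random_seq(rng, config.promoter_length) for g in prom_genes
    }

    # one pyrimidine tract (DNA-binding domain) per lncRNA, reused for all
    # of its target promoters
    lnc_tracts: dict[str, tuple[int, np.ndarray]] = {}
    bed_rows = []
    for lnc, gene in config.tract_map:
        if lnc not in lnc_tracts:
            tract = rng.choice(list(PYRIMIDINES), size=config.tract_length)
            start = int(rng.integers(0, config.lnc_length - config.tract_length + 1))
            lnc_seqs[lnc][start: start + config.tract_length] = tract
            lnc_tracts[lnc] = (start, tract)
        lnc_start, tract = lnc_tracts[lnc]
        purine = np.array([_PUR_FOR_PYR[b] for b in tract])
        dstart = int(rng.integers(0, config.promoter_length - config.tract_length + 1))
        prom_seqs[gene][dstart: dstart + config.tract_length] = purine
        bed_rows.append(
            (gene, dstart, dstart + config.tract_length, lnc, config.tract_length, "+")
        )

    bed = pd.DataFrame(
        bed_rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )
    return (
        {k: "".join(v) for k, v in lnc_seqs.items()},
        {k: "".join(v) for k, v in prom_seqs.items()},
        bed,
    )
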