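"""Seeded synthetic datasets with the statistical structure the pipeline assumes.

The generator emulates four coupled layers of a multi-tissue translatome
study:

1. **CDS sequences** — per gene, amino acids drawn uniformly over the 18
   multi-codon amino acids (Met/Trp at a low rate), and within each family
   a C/G-ending codon chosen with probability ``logistic(b_g)`` where
   ``b_g ~ Uniform(-1, 1)`` is the gene's GC3 bias; codons uniform within
   the ending class.  An initiator ATG and a terminal TAA frame each gene.
2. **Modification abundances** — area ratios
   ``a[m,t,r] = exp(log(base_m) + tau * Ztrue[m,t] + eps)`` with replicate
   noise ``eps ~ Normal(0, sigma_rep)``.  The default true Z-profiles put
   queuosine (Q) highest in brain and lowest in liver/spleen, with its
   derivatives and the mcm5U cluster following plausible tissue patterns.
3. **Decoding efficiency and expression** — Q-family C-ending codons decode
   with efficiency ``e[c,t] = exp(beta_C * Ztrue[Q,t])``, their T-ending
   partners with ``exp(beta_U * Ztrue[Q,t])``, all others 1; expression
   couples to codon content through
   ``log x[g,t] = log(base_g) + alpha * sum_c f[g,c] * (e[c,t]-1) + noise``.
4. **Footprints** — per tissue, footprint totals per gene proportional to
   expression; within a gene the A-site codon is drawn with probability
   proportional to dwell ``d[c,t] = 1 / e[c,t]`` per codon occurrence, and
   the 5' start is back-computed from the same offset table the pausing
   module uses, so assignment round-trips exactly.

Ground truth (Z-profiles, efficiencies, dwell, GC3 biases) is carried in
the dataset for recovery tests.  All randomness flows from one
``numpy.random.default_rng(seed)`` (PCG64) stream.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genetic_code import CodingSequence, CodonTable, build_codon_table
from .pausing import DEFAULT_OFFSETS

DEFAULT_TISSUES = ("brain", "heart", "muscle", "kidney", "liver", "lung", "spleen")

#: true tissue Z-profiles of the wired-in modifications (brain-high Q cluster,
#: liver/spleen-low, lung sharing mcm5U with brain, flat galQ)
DEFAULT_Z_TRUE: dict[str, dict[str, float]] = {
    "Q": dict(zip(DEFAULT_TISSUES, (1.8, 0.5, 0.2, 0.0, -1.2, -0.1, -1.2))),
    "manQ": dict(zip(DEFAULT_TISSUES, (1.6, 0.4, 0.1, 0.2, -1.1, -0.2, -1.0))),
    "galQ": dict(zip(DEFAULT_TISSUES, (0.2, -0.3, 0.1, 0.4, -0.2, 0.1, -0.3))),
    "mcm5U": dict(zip(DEFAULT_TISSUES, (1.5, 0.3, 0.2, -0.3, -1.0, 1.2, -0.8))),
    "mcm5s2U": dict(zip(DEFAULT_TISSUES, (0.8, 0.9, 0.7, -0.4, -0.9, -0.5, -0.6))),
}

_BASE_AREA = {"Q": 0.02, "manQ": 0.004, "galQ": 0.003, "mcm5U": 0.01, "mcm5s2U": 0.008}

#: C-ending queuosine codons and their T-ending partners
NAC_CODONS = ("AAC", "GAC", "CAC", "TAC")
NAT_CODONS = ("AAT", "GAT", "CAT", "TAT")


class SimulationError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-scale defaults: 7 tissues, 1000 genes of 300 codons, 4 LC-MS/MS
    replicates, 1e5 footprints per tissue."""

    tissues: tuple[str, ...] = DEFAULT_TISSUES
    n_genes: int = 1000
    gene_length: int = 300  # coding codons incl. initiator, excl. STOP
    beta_c: float = 0.8  # Q effect on C-ending NAY decoding (log scale)
    beta_u: float = -0.2  # Q effect on T-ending NAY decoding
    z_true: dict[str, dict[str, float]] = field(
        default_factory=lambda: {m: dict(v) for m, v in DEFAULT_Z_TRUE.items()}
    )
    extra_modifications: tuple[str, ...] = ("m1A", "m5C", "m7G", "Um", "t6A")
    sigma_rep: float = 0.1  # replicate noise SD, log scale
    n_replicates: int = 4
    tau: float = 0.5  # log-area units per true Z unit
    alpha: float = 2.0  # expression coupling to codon-content decoding gain
    sigma_expr: float = 0.3  # expression noise SD, log scale
    footprints_per_tissue: int = 100_000
    met_trp_rate: float = 0.05
    couple_mcm5u: bool = False
    beta_mcm5u: float = 0.4
    min_gene_set: int = 200

    def validate(self) -> None:
        if len(set(self.tissues)) != len(self.tissues):
            raise SimulationError("tissue names must be unique")
        if min(self.sigma_rep, self.sigma_expr) < 0:
            raise SimulationError("noise SDs must be non-negative")
        if self.n_genes < 2 * self.min_gene_set:
            raise SimulationError(
                f"n_genes={self.n_genes} cannot supply disjoint top/bottom "
                f"sets of {self.min_gene_set}"
            )
        if self.gene_length < 20:
            raise SimulationError("gene_length must be at least 20 codons")
        for mod, prof in self.z_true.items():
            if set(prof) != set(self.tissues):
                raise SimulationError(f"Z profile of {mod} does not cover all tissues")


@dataclass
class SyntheticDataset:
    """Generated inputs plus the ground truth that produced them."""

    config: GeneratorConfig
    seed: int
    cds: list[CodingSequence]
    expression: pd.DataFrame  # genes x tissues
    modifications: pd.DataFrame  # long: modification, tissue, replicate, area_ratio
    footprints: dict[str, pd.DataFrame]  # tissue -> gene_id, start, length
    truth: dict

    def write(self, outdir) -> None:
        """Serialize as cds.fasta, expression.tsv, modifications.tsv,
        footprints_<tissue>.tsv, truth.json under one directory."""
        from .genetic_code import write_cds_fasta

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_cds_fasta(out / "cds.fasta", self.cds)
        self.expression.to_csv(out / "expression.tsv", sep="\t", index_label="gene_id")
        self.modifications.to_csv(out / "modifications.tsv", sep="\t", index=False)
        for tissue, fp in self.footprints.items():
            fp.to_csv(out / f"footprints_{tissue}.tsv", sep="\t", index=False)
        serializable = {
            "seed": self.seed,
            "rng": "numpy.random.default_rng (PCG64)",
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(self.config).items()
            },
            "z_true": {
                m: dict(row) for m, row in self.truth["z_true"].iterrows()
            },
            "efficiency": {
                c: dict(row) for c, row in self.truth["efficiency"].iterrows()
            },
            "gc3_bias": dict(
                zip(self.expression.index, map(float, self.truth["gc3_bias"]))
            ),
        }
        (out / "truth.json").write_text(json.dumps(serializable, indent=1))


def _amino_acid_class_members(table: CodonTable) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """aa -> (AT-ending member codon indices, GC-ending member indices)."""
    pos = {c: i for i, c in enumerate(table.codons)}
    out = {}
    for aa, fam in table.families.items():
        at = np.array([pos[c] for c in fam if c[2] in "AT"], dtype=np.int64)
        gc = np.array([pos[c] for c in fam if c[2] in "GC"], dtype=np.int64)
        if len(fam) == 1:  # Met/Trp: single codon regardless of class draw
            at = gc = np.array([pos[fam[0]]], dtype=np.int64)
        out[aa] = (at, gc)
    return out


def efficiency_matrix(config: GeneratorConfig, table: CodonTable) -> pd.DataFrame:
    """True decoding efficiency e[c, t] for all 64 codons."""
    z_q = pd.Series(config.z_true["Q"])[list(config.tissues)]
    eff = pd.DataFrame(1.0, index=list(table.codons), columns=list(config.tissues))
    for codon in NAC_CODONS:
        eff.loc[codon] = np.exp(config.beta_c * z_q.to_numpy())
    for codon in NAT_CODONS:
        eff.loc[codon] = np.exp(config.beta_u * z_q.to_numpy())
    if config.couple_mcm5u:
        z_m = pd.Series(config.z_true["mcm5U"])[list(config.tissues)]
        for codon in table.rule_sets["mcm5U"]:
            eff.loc[codon] = eff.loc[codon].to_numpy() * np.exp(
                config.beta_mcm5u * z_m.to_numpy()
            )
    eff.index.name = "codon"
    return eff


def generate(config: GeneratorConfig | None = None, seed: int = 0) -> SyntheticDataset:
    """Generate a full synthetic dataset, deterministic given ``seed``."""
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    table = build_codon_table("DNA")
    tissues = list(config.tissues)
    n_genes, length = config.n_genes, config.gene_length
    codon_arr = np.array(table.codons)

    # ---- 1. sequences -----------------------------------------------------
    gc3_bias = rng.uniform(-1.0, 1.0, size=n_genes)
    p_cg = 1.0 / (1.0 + np.exp(-gc3_bias))

    multi_aas = sorted(aa for aa, fam in table.families.items() if len(fam) > 1)
    aa_mat = np.array(multi_aas, dtype="<U1")[
        rng.integers(0, len(multi_aas), size=(n_genes, length))
    ]
    mw_mask = rng.random((n_genes, length)) < config.met_trp_rate
    mw_pick = np.where(rng.random((n_genes, length)) < 0.5, "M", "W")
    aa_mat = np.where(mw_mask, mw_pick, aa_mat)
    aa_mat[:, 0] = "M"  # initiator

    is_cg = rng.random((n_genes, length)) < p_cg[:, None]
    u_member = rng.random((n_genes, length))
    codon_idx = np.zeros((n_genes, length), dtype=np.int64)
    members_by_aa = _amino_acid_class_members(table)
    for aa, (at_members, gc_members) in members_by_aa.items():
        for members, cls in ((at_members, False), (gc_members, True)):
            mask = (aa_mat == aa) & (is_cg == cls)
            if not mask.any():
                continue
            pick = np.minimum(
                (u_member[mask] * len(members)).astype(np.int64), len(members) - 1
            )
            codon_idx[mask] = members[pick]

    width = len(str(n_genes))
    gene_ids = [f"g{i + 1:0{width}d}" for i in range(n_genes)]
    body = codon_arr[codon_idx]
    cds = [
        CodingSequence(gid, "".join(row) + "TAA")
        for gid, row in zip(gene_ids, body)
    ]

    counts = np.zeros((n_genes, 64), dtype=np.int64)
    np.add.at(
        counts,
        (np.repeat(np.arange(n_genes), length), codon_idx.ravel()),
        1,
    )
    total_freq = counts / length  # body has no STOPs

    # ---- 2. modification abundances ---------------------------------------
    z_true = pd.DataFrame(config.z_true).T[tissues]
    for mod in config.extra_modifications:
        if mod not in z_true.index:
            z_true.loc[mod] = rng.normal(0.0, 1.0, size=len(tissues))
    z_true.index.name = "modification"
    rows = []
    for mod in z_true.index:
        base = _BASE_AREA.get(mod, 0.005)
        for tissue in tissues:
            eps = rng.normal(0.0, config.sigma_rep, size=config.n_replicates)
            areas = np.exp(
                np.log(base) + config.tau * z_true.loc[mod, tissue] + eps
            )
            rows.extend(
                {
                    "modification": mod,
                    "tissue": tissue,
                    "replicate": r + 1,
                    "area_ratio": float(a),
                }
                for r, a in enumerate(areas)
            )
    modifications = pd.DataFrame(rows)

    # ---- 3. decoding efficiency and expression ----------------------------
    eff = efficiency_matrix(config, table)
    gain = total_freq @ (eff.to_numpy() - 1.0)  # genes x tissues
    log_base = rng.normal(np.log(1000.0), 1.0, size=n_genes)
    log_x = (
        log_base[:, None]
        + config.alpha * gain
        + rng.normal(0.0, config.sigma_expr, size=(n_genes, len(tissues)))
    )
    expression = pd.DataFrame(np.exp(log_x), index=gene_ids, columns=tissues)
    expression.index.name = "gene_id"

    # ---- 4. footprints -----------------------------------------------------
    dwell = 1.0 / eff.to_numpy()  # 64 x tissues
    footprints: dict[str, pd.DataFrame] = {}
    if config.footprints_per_tissue > 0:
        # codon indices where every 28-31 nt fragment fits with the default
        # offsets (start >= 0 needs 3i >= 16; 3' end inside CDS incl. STOP)
        allowed = np.arange(6, length - 3)
        for t_i, tissue in enumerate(tissues):
            w = expression[tissue].to_numpy()[:, None] * dwell[
                codon_idx[:, allowed], t_i
            ]
            p = (w / w.sum()).ravel()
            cell_counts = rng.multinomial(config.footprints_per_tissue, p)
            nz = np.nonzero(cell_counts)[0]
            reps = cell_counts[nz]
            genes = np.repeat(nz // len(allowed), reps)
            pos = np.repeat(allowed[nz % len(allowed)], reps)
            lengths = rng.integers(28, 32, size=pos.size)
            offsets = np.where(lengths == 31, 16, 15)
            starts = 3 * pos - offsets
            footprints[tissue] = pd.DataFrame(
                {
                    "gene_id": np.array(gene_ids, dtype=object)[genes],
                    "start": starts,
                    "length": lengths,
                }
            )

    truth = {
        "z_true": z_true,
        "efficiency": eff,
        "dwell": pd.DataFrame(dwell, index=list(table.codons), columns=tissues),
        "gc3_bias": gc3_bias,
        "offsets": dict(DEFAULT_OFFSETS),
    }
    return SyntheticDataset(
        config=config,
        seed=seed,
        cds=cds,
        expression=expression,
        modifications=modifications,
        footprints=footprints,
        truth=truth,
    )


def dwell_log2_ratio(dataset: SyntheticDataset, tissue_a: str, tissue_b: str) -> pd.Series:
    """True per-codon log2(dwell_A / dwell_B) — the target of pause log2FC."""
    d = dataset.truth["dwell"]
    out = np.log2(d[tissue_a] / d[tissue_b])
    out.name = f"true_log2_dwell_{tissue_a}_vs_{tissue_b}"
    return out


def recovery_report(
    dataset: SyntheticDataset,
    *,
    z_est: pd.DataFrame | None = None,
    pause_log2fc: dict[str, pd.Series] | None = None,
    reference_tissue: str = "brain",
    codons: list[str] | None = None,
) -> pd.DataFrame:
    """Ground truth vs pipeline estimates, one row per comparison.

    ``z_est`` — estimated modification x tissue Z-scores; each modification
    row is correlated with its true profile.  ``pause_log2fc`` — tissue ->
    estimated per-codon log2FC (reference vs that tissue); compared against
    the true log2 dwell ratio over ``codons`` (default: the eight Q-family
    codons).  Pearson r of truth vs estimate is reported per comparison.
    """
    rows = []
    if z_est is not None:
        z_true = dataset.truth["z_true"]
        for mod in z_est.index:
            if mod not in z_true.index:
                continue
            a = z_true.loc[mod, z_est.columns].to_numpy(float)
            b = z_est.loc[mod].to_numpy(float)
            if np.std(a) == 0 or np.std(b) == 0:
                continue
            rows.append(
                {
                    "layer": "modification_z",
                    "name": mod,
                    "r": float(np.corrcoef(a, b)[0, 1]),
                    "n": len(a),
                }
            )
    if pause_log2fc is not None:
        if codons is None:
            codons = sorted(NAC_CODONS + NAT_CODONS)
        for tissue, est in pause_log2fc.items():
            truth = dwell_log2_ratio(dataset, reference_tissue, tissue)
            joined = pd.concat([truth, est], axis=1, join="inner").loc[codons].dropna()
            if len(joined) < 3:
                continue
            a, b = joined.iloc[:, 0].to_numpy(), joined.iloc[:, 1].to_numpy()
            rows.append(
                {
                    "layer": "pause_log2fc",
                    "name": f"{reference_tissue}_vs_{tissue}",
                    "r": float(np.corrcoef(a, b)[0, 1]),
                    "n": len(joined),
                }
            )
    return pd.DataFrame(rows, columns=["layer", "name", "r", "n"])
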