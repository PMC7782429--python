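"""Synthetic communities with the statistical structure the analysis assumes.

The generator emulates the study design downstream stages are built for:
two diet groups (true-protein control ``TP`` vs urea-supplemented ``US``)
with six animals each, a community of species whose genomes are KO sets,
negative-binomial gene counts with planted group fold-changes, scaffolds of
1–5 genes, genome bins with controlled completeness/contamination/strain
heterogeneity, and an environment table optionally coupled to community
composition.  Every planted effect is recorded in ``SyntheticTruth`` so
recovery can be scored exactly; identical seeds reproduce byte-identical
bundles.

Counts are NB(mean µ, dispersion α) with variance µ + α·µ²;
µ = species baseline × group fold-change × (gene length / 1000) × per-sample
depth factor, depth factors lognormal(0, 0.1) so that raw counts are not
comparable across samples and TPM normalization is genuinely exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .community import BinRecord
from .markers import MarkerCatalog, default_marker_catalog
from .pathways import PathwayDef, default_pathway_definitions

__all__ = [
    "SyntheticTruth",
    "SyntheticBundle",
    "generate_community",
    "generate_bins",
    "generate_env_table",
    "mutate_sequence",
]

GROUP_LABELS = ("TP", "US")

#: default enzyme complements planted into successive marker species,
#: cycling; patterns mirror the complements seen in marker-community tables.
DEFAULT_MARKER_COMPLEMENTS: tuple[tuple[str, ...], ...] = (
    ("ACS",),
    ("GLO",),
    ("ACS", "HYD", "GLO", "LAR"),
    ("HYD", "GLO", "LAR"),
    ("URE",),
    ("HYD", "LAR"),
    ("GLO",),
    ("HYD", "GLO"),
    ("LAR",),
    ("URE", "GLO"),
)

_BASES = np.array(list("ACGT"))


@dataclass
class SyntheticTruth:
    """Ground truth of a synthetic community."""

    species_table: pd.DataFrame  # species_id, baseline, kos, enzymes
    effect_table: pd.Series      # species_id -> group fold-change
    gene_table: pd.DataFrame     # gene_id, species_id, length, ko
    group_design: pd.Series      # sample_id -> group label
    seed: int

    def expected_relative_fold(self) -> pd.Series:
        """Expected treatment/control fold-change on the relative (TPM) scale.

        TPM is compositional: a planted absolute fold-change ``f_s`` shows
        up relative to the community-wide shift
        ``F = sum_i(n_i b_i f_i) / sum_i(n_i b_i)`` (n = gene count,
        b = baseline), so the expected relative fold is ``f_s / F``.  Gene
        lengths cancel because the NB mean is proportional to length while
        TPM divides it back out.
        """
        n_genes = self.gene_table.groupby("species_id").size()
        b = self.species_table["baseline"]
        f = self.effect_table
        weight = n_genes * b
        community_shift = (weight * f).sum() / weight.sum()
        return (f / community_shift).rename("relative_fold")

    def expected_relative_directions(self, tol: float = 1e-9) -> pd.Series:
        """Truth labels for the population partition, on the relative scale."""
        rel = self.expected_relative_fold()
        labels = np.where(
            rel > 1 + tol, "upregulated",
            np.where(rel < 1 - tol, "downregulated", "unchanged"),
        )
        return pd.Series(labels, index=rel.index, name="population")


@dataclass
class SyntheticBundle:
    """Everything downstream stages consume, plus the generating truth."""

    gene_counts: pd.DataFrame            # genes × samples, integers
    gene_table: pd.DataFrame             # gene_id, species_id, length, ko
    scaffold_table: pd.DataFrame         # scaffold_id, species_id, genes
    sequences: dict[str, str]            # marker-gene sequences
    truth: SyntheticTruth
    bin_table: list[BinRecord] = field(default_factory=list)
    env_table: pd.DataFrame | None = None

    @property
    def ko_map(self) -> dict[str, str]:
        return dict(zip(self.gene_table["gene_id"], self.gene_table["ko"]))

    @property
    def gene_lengths(self) -> pd.Series:
        return self.gene_table.set_index("gene_id")["length"]

    @property
    def scaffold_genes(self) -> dict[str, tuple[str, ...]]:
        return dict(zip(self.scaffold_table["scaffold_id"], self.scaffold_table["genes"]))

    @property
    def gene_scaffold(self) -> dict[str, str]:
        return {
            g: sc
            for sc, genes in self.scaffold_genes.items()
            for g in genes
        }

    def scaffold_counts(self) -> pd.DataFrame:
        """Scaffold counts = sum of member-gene counts."""
        rows = {
            sc: self.gene_counts.loc[list(genes)].sum(axis=0)
            for sc, genes in self.scaffold_genes.items()
        }
        return pd.DataFrame(rows).T

    def scaffold_lengths(self) -> pd.Series:
        lengths = self.gene_lengths
        return pd.Series(
            {
                sc: float(lengths.loc[list(genes)].sum())
                for sc, genes in self.scaffold_genes.items()
            }
        )

    def species_counts(self) -> pd.DataFrame:
        """Species × sample summed gene counts."""
        return self.gene_counts.groupby(self.gene_table.set_index("gene_id")["species_id"]).sum()


def mutate_sequence(sequence: str, divergence: float, rng: np.random.Generator) -> str:
    """Substitute an exact fraction of positions with a different base."""
    if not 0.0 <= divergence < 1.0:
        raise ValueError(f"divergence must be in [0, 1), got {divergence}")
    seq = np.array(list(sequence))
    n_mut = int(round(divergence * len(seq)))
    if n_mut == 0:
        return sequence
    positions = rng.choice(len(seq), size=n_mut, replace=False)
    for pos in positions:
        choices = [b for b in "ACGT" if b != seq[pos]]
        seq[pos] = choices[rng.integers(0, 3)]
    return "".join(seq)


def _species_kos(
    rng: np.random.Generator,
    pathway_defs: Sequence[PathwayDef],
    n_filler: int = 40,
) -> list[str]:
    """Draw a species' KO repertoire: a random share of the pathway KO
    universe plus filler KOs outside every pathway."""
    universe = sorted({ko for p in pathway_defs for ko in p.kos})
    share = rng.uniform(0.4, 0.8)
    kos = [ko for ko in universe if rng.random() < share]
    fillers = [f"K9{i:04d}" for i in range(n_filler)]
    kos += [ko for ko in fillers if rng.random() < 0.3]
    return kos


def generate_community(
    n_species: int = 20,
    n_per_group: int = 6,
    effect_spec: Mapping[str, float] | None = None,
    nb_dispersion: float = 0.05,
    seed: int = 0,
    marker_spec: Mapping[str, Sequence[str]] | None = None,
    divergence: float = 0.08,
    depth_sd: float = 0.1,
    catalog: MarkerCatalog | None = None,
    pathway_defs: Sequence[PathwayDef] | None = None,
    with_bins: bool = True,
    with_env: bool = True,
) -> SyntheticBundle:
    """Generate a synthetic two-group community.

    ``effect_spec`` maps species ids (``S01``…) to strictly positive
    fold-changes applied in the second (treatment) group; unlisted species
    have fold-change 1.  ``marker_spec`` maps species ids to the marker
    enzymes planted in their genomes; by default roughly 60% of species
    receive complements cycling through ``DEFAULT_MARKER_COMPLEMENTS``.
    Planted marker genes diverge ``divergence`` (default 8%) from their
    catalog reference: comfortably inside the >85%-identity retrieval gate
    while keeping independently mutated copies of the same reference
    mutually below the 90% NR-clustering threshold, so each planted species
    keeps its own marker gene.  Deterministic under ``seed``.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if nb_dispersion <= 0:
        raise ValueError("nb_dispersion must be > 0")
    rng = np.random.default_rng(seed)
    catalog = catalog or default_marker_catalog()
    pathway_defs = list(pathway_defs or default_pathway_definitions())

    species_ids = [f"S{i + 1:02d}" for i in range(n_species)]
    effects = pd.Series(1.0, index=species_ids, name="fold_change")
    if effect_spec:
        for sp, fold in effect_spec.items():
            if sp not in effects.index:
                raise ValueError(f"unknown species in effect_spec: {sp}")
            if fold <= 0:
                raise ValueError(
                    f"non-positive fold-change {fold} for species {sp}"
                )
            effects[sp] = float(fold)

    if marker_spec is None:
        n_marked = max(1, int(round(0.6 * n_species)))
        marker_spec = {
            species_ids[i]: DEFAULT_MARKER_COMPLEMENTS[
                i % len(DEFAULT_MARKER_COMPLEMENTS)
            ]
            for i in range(n_marked)
        }
    for sp in marker_spec:
        if sp not in species_ids:
            raise ValueError(f"unknown species in marker_spec: {sp}")

    samples = [f"{g}{i + 1}" for g in GROUP_LABELS for i in range(n_per_group)]
    group_design = pd.Series(
        [g for g in GROUP_LABELS for _ in range(n_per_group)],
        index=samples,
        name="group",
    )

    enzyme_counter: dict[str, int] = {}
    gene_rows = []
    sequences: dict[str, str] = {}
    species_rows = []
    for sp in species_ids:
        baseline = float(rng.lognormal(mean=3.0, sigma=0.7))
        kos = _species_kos(rng, pathway_defs)
        enzymes = tuple(marker_spec.get(sp, ()))
        for j, ko in enumerate(kos):
            gene_rows.append(
                (f"{sp}_g{j + 1:03d}", sp, int(rng.integers(300, 1501)), ko)
            )
        for enzyme in enzymes:
            enzyme_kos = catalog.enzyme_kos[enzyme]
            idx = enzyme_counter.get(enzyme, 0)
            enzyme_counter[enzyme] = idx + 1
            ko = enzyme_kos[idx % len(enzyme_kos)]
            ref = catalog.references[enzyme][f"{enzyme}_{ko}_ref"]
            seq = mutate_sequence(ref, divergence, rng)
            gene_id = f"{sp}_mk_{enzyme}"
            gene_rows.append((gene_id, sp, len(seq), ko))
            sequences[gene_id] = seq
        species_rows.append((sp, baseline, frozenset(kos), enzymes))

    gene_table = pd.DataFrame(
        gene_rows, columns=["gene_id", "species_id", "length", "ko"]
    )
    species_table = pd.DataFrame(
        species_rows, columns=["species_id", "baseline", "kos", "enzymes"]
    ).set_index("species_id", drop=False)

    # scaffolds: each species' genes partitioned into runs of 1-5 genes
    scaffold_rows = []
    for sp in species_ids:
        genes = gene_table.loc[gene_table["species_id"] == sp, "gene_id"].tolist()
        order = rng.permutation(len(genes))
        genes = [genes[i] for i in order]
        i = k = 0
        while i < len(genes):
            size = int(rng.integers(1, 6))
            scaffold_rows.append(
                (f"{sp}_sc{k + 1:03d}", sp, tuple(genes[i : i + size]))
            )
            i += size
            k += 1
    scaffold_table = pd.DataFrame(
        scaffold_rows, columns=["scaffold_id", "species_id", "genes"]
    )

    # NB counts: mean = baseline * fold * (length/1000) * depth
    depth = rng.lognormal(mean=0.0, sigma=depth_sd, size=len(samples))
    baseline_per_gene = species_table.loc[gene_table["species_id"], "baseline"].to_numpy()
    fold_per_gene = effects.loc[gene_table["species_id"]].to_numpy()
    length_factor = gene_table["length"].to_numpy() / 1000.0
    is_treatment = (group_design.values == GROUP_LABELS[1]).astype(float)
    mu = (
        baseline_per_gene[:, None]
        * np.where(is_treatment[None, :] > 0, fold_per_gene[:, None], 1.0)
        * length_factor[:, None]
        * depth[None, :]
    )
    n_param = 1.0 / nb_dispersion
    p_param = n_param / (n_param + mu)
    counts = rng.negative_binomial(n_param, p_param)
    gene_counts = pd.DataFrame(
        counts, index=gene_table["gene_id"].tolist(), columns=samples
    )

    truth = SyntheticTruth(species_table, effects, gene_table, group_design, seed)
    bundle = SyntheticBundle(
        gene_counts, gene_table, scaffold_table, sequences, truth
    )
    if with_bins:
        bundle.bin_table = generate_bins(bundle, seed=seed + 1)
    if with_env:
        bundle.env_table = generate_env_table(bundle, seed=seed + 2)
    return bundle


def generate_bins(
    bundle: SyntheticBundle,
    completeness_range: tuple[float, float] = (70.0, 100.0),
    contamination_rate: float = 0.0,
    heterogeneity_rate: float = 0.0,
    seed: int = 0,
    bins_per_species: int = 1,
    quality_noise_sd: float = 0.0,
) -> list[BinRecord]:
    """Sample bins from a bundle's scaffolds with controlled quality.

    Each bin draws the completeness fraction of one species' scaffolds
    (rounding down) plus contaminant scaffolds from other species'
    still-unbinned scaffolds; recorded completeness and contamination equal
    the realized fractions (optionally Gaussian-perturbed with
    ``quality_noise_sd``, clipped to [0, 100]).  A scaffold never appears
    in two bins.
    """
    lo, hi = completeness_range
    if not 0.0 <= lo <= hi <= 100.0:
        raise ValueError(f"invalid completeness_range {completeness_range}")
    if contamination_rate >= 100.0 or contamination_rate < 0.0:
        raise ValueError(
            f"contamination_rate must be in [0, 100), got {contamination_rate}"
        )
    rng = np.random.default_rng(seed)
    by_species = {
        sp: sub["scaffold_id"].tolist()
        for sp, sub in bundle.scaffold_table.groupby("species_id", sort=True)
    }
    species_ids = sorted(by_species)
    used: set[str] = set()
    bins: list[BinRecord] = []
    for sp in species_ids:
        pool = [s for s in by_species[sp]]
        order = rng.permutation(len(pool))
        pool = [pool[i] for i in order]
        n_total = len(pool)
        taken_so_far = 0
        for b in range(bins_per_species):
            c = float(rng.uniform(lo, hi))
            n_take = int(np.floor(c / 100.0 * n_total))
            n_take = min(n_take, n_total - taken_so_far)
            if n_take == 0:
                continue
            own = pool[taken_so_far : taken_so_far + n_take]
            taken_so_far += n_take
            used.update(own)
            realized_completeness = 100.0 * n_take / n_total

            n_cont = int(round(contamination_rate / 100.0 * n_take))
            contaminants: list[str] = []
            if n_cont > 0:
                foreign = [
                    s
                    for other, scs in by_species.items()
                    if other != sp
                    for s in scs
                    if s not in used
                ]
                pick = rng.permutation(len(foreign))[:n_cont]
                contaminants = [foreign[i] for i in pick]
                used.update(contaminants)
            realized_contamination = 100.0 * len(contaminants) / n_take
            heterogeneity = float(heterogeneity_rate)
            comp, cont, het = realized_completeness, realized_contamination, heterogeneity
            if quality_noise_sd > 0:
                comp, cont, het = (
                    float(np.clip(v + rng.normal(0, quality_noise_sd), 0, 100))
                    for v in (comp, cont, het)
                )
            bins.append(
                BinRecord(
                    bin_id=f"bin_{sp}_{b + 1}",
                    scaffolds=tuple(own + contaminants),
                    completeness=comp,
                    contamination=cont,
                    strain_heterogeneity=het,
                    species=sp,
                )
            )
    return bins


def generate_env_table(
    bundle: SyntheticBundle,
    coupled_axis: np.ndarray | Sequence[float] | None = None,
    noise_sd: float = 0.1,
    seed: int = 0,
    coupled_var: str = "ammonia_mM",
) -> pd.DataFrame:
    """Generate an environment/fermentation table for a bundle's samples.

    One variable (``coupled_var``) is a linear projection of per-sample
    species composition onto ``coupled_axis`` plus Gaussian noise; the
    remaining variables are independent noise around rumen-typical values.
    The planted gradient is stored in ``result.attrs["gradient"]``.
    """
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    rng = np.random.default_rng(seed)
    comp = bundle.species_counts().T  # samples × species
    comp = comp.div(comp.sum(axis=1), axis=0)
    n_species = comp.shape[1]
    if coupled_axis is None:
        coupled_axis = rng.standard_normal(n_species)
    loading = np.asarray(coupled_axis, dtype=float)
    if loading.shape != (n_species,):
        raise ValueError(
            f"coupled_axis length {loading.size} != n_species {n_species}"
        )
    gradient = pd.Series(comp.to_numpy() @ loading, index=comp.index, name="gradient")
    z = gradient - gradient.mean()
    scale = z.std(ddof=0)
    if scale > 0:
        z = z / scale

    samples = comp.index
    n = len(samples)
    base = {
        "pH": (6.7, 0.05),
        "ammonia_mM": (14.0, 1.5),
        "ni_uM": (10.0, 1.0),
        "acetate_mM": (53.0, 2.0),
        "propionate_mM": (19.5, 1.5),
        "butyrate_mM": (12.0, 1.0),
        "l_lactate_mM": (0.60, 0.05),
        "d_lactate_mM": (0.45, 0.05),
    }
    if coupled_var not in base:
        raise ValueError(f"unknown coupled_var '{coupled_var}'")
    env = pd.DataFrame(index=samples)
    env["group"] = bundle.truth.group_design.loc[samples]
    for var, (mu, sd) in base.items():
        if var == coupled_var:
            env[var] = mu + sd * z.to_numpy() + rng.normal(0.0, noise_sd, n)
        else:
            env[var] = mu + rng.normal(0.0, sd, n)
        if var != "pH":
            env[var] = env[var].clip(lower=0.01)
        else:
            env[var] = env[var].clip(lower=0.1, upper=13.9)
    env.index.name = "sample"
    env.attrs["gradient"] = gradient
    return env
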