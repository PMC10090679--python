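"""Synthetic esophageal-epithelium data with known ground truth.

The generator emulates the structure the downstream analysis assumes:

* 13 keratinocyte populations in three strata — 5 basal (B1–B5), 6 suprabasal
  (SB1–SB6), 2 superficial (S1, S2) — with negative-binomial UMI counts around
  per-population gene means;
* a Krt5/Krtdap marker gradient (basal: Krt5 ≫ Krtdap; superficial: the
  reverse; suprabasal: the two within a narrow ratio) so the slope-1 strip
  classifier has a planted answer;
* cell-cycle programs: population B2 up-regulates a 20-gene S-phase set and
  B3 a 20-gene G2M set (4x by default), everything else rests in G1/G0;
* block co-expression gene modules driven by per-cell latent factors, some
  blocks additionally up-regulated in specific populations;
* condition-dependent proportions — EoE expands SB2–SB5 and depletes B1–B2;
  ESCC expands B1, B5, SB6 and depletes SB1, SB4 — over replicates of
  6 control, 3 EoE and 4 ESCC mice;
* QC-violating cells: low-count debris and high-count doublets.

Truth labels are always emitted next to the counts and are never consumed by
the pipeline itself.

A separate generator produces the in vivo tumor-study table: four treatment
groups (vehicle, EoE-only, carcinogen-only, EoE+carcinogen) with Poisson
tumor counts, Gamma tumor areas, lesion grades, and percent neoplastic
epithelium; EoE exposure scales the tumor-initiation rate down by the effect
factor and forbids invasive carcinoma in the combination group.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix

__all__ = [
    "PopulationSpec",
    "SynthSpec",
    "SynthResult",
    "generate_dataset",
    "simulate_proportion_counts",
    "generate_module_blocks",
    "generate_tumor_study",
    "default_cycle_genes",
]

CONDITIONS = ("control", "EoE", "ESCC")
STRATA = ("basal", "suprabasal", "superficial")


def default_cycle_genes(which: str) -> list[str]:
    """Shipped murine S / G2M phase marker lists (editable text files)."""
    fname = {"S": "s_genes.txt", "G2M": "g2m_genes.txt"}[which]
    text = resources.files("esostrata.data").joinpath(fname).read_text()
    return [g.strip() for g in text.splitlines() if g.strip()]


@dataclass
class PopulationSpec:
    name: str
    stratum: str  # basal | suprabasal | superficial
    proportions: dict  # condition -> baseline proportion
    krt5_mean: float
    krtdap_mean: float
    cycling: str = "none"  # none | S | G2M

    def __post_init__(self) -> None:
        if self.stratum not in STRATA:
            raise ValueError(f"unknown stratum {self.stratum!r}")
        if any(p < 0 for p in self.proportions.values()):
            raise ValueError("population proportions must be >= 0")


def _default_populations() -> list[PopulationSpec]:
    # control baseline weights; EoE and ESCC apply fold-changes then renormalize
    base = {
        "B1": 0.10, "B2": 0.10, "B3": 0.09, "B4": 0.07, "B5": 0.03,
        "SB1": 0.10, "SB2": 0.07, "SB3": 0.07, "SB4": 0.08, "SB5": 0.06,
        "SB6": 0.03, "S1": 0.12, "S2": 0.08,
    }
    eoe_fc = {"SB2": 3.0, "SB3": 3.0, "SB4": 3.0, "SB5": 3.0, "B1": 0.3, "B2": 0.3}
    escc_fc = {"B1": 3.0, "B5": 3.0, "SB6": 3.0, "SB1": 0.3, "SB4": 0.3}

    def norm(weights: dict) -> dict:
        tot = sum(weights.values())
        return {k: v / tot for k, v in weights.items()}

    eoe = norm({k: v * eoe_fc.get(k, 1.0) for k, v in base.items()})
    escc = norm({k: v * escc_fc.get(k, 1.0) for k, v in base.items()})

    # suprabasal Krt5/Krtdap ratios stay inside the strip; basal/superficial
    # dominate one marker
    sb_ratio = {"SB1": 1.0, "SB2": 1.15, "SB3": 0.9, "SB4": 1.1, "SB5": 0.85, "SB6": 1.0}
    pops = []
    for name in base:
        if name.startswith("B"):
            stratum, k5, kd = "basal", 25.0, 0.6
        elif name.startswith("SB"):
            r = sb_ratio[name]
            stratum, k5, kd = "suprabasal", 8.0 * r, 8.0 / r
        else:
            stratum, k5, kd = "superficial", 0.6, 25.0
        cycling = {"B2": "S", "B3": "G2M"}.get(name, "none")
        pops.append(
            PopulationSpec(
                name=name,
                stratum=stratum,
                proportions={"control": base[name], "EoE": eoe[name], "ESCC": escc[name]},
                krt5_mean=k5,
                krtdap_mean=kd,
                cycling=cycling,
            )
        )
    return pops


@dataclass
class SynthSpec:
    """Study design of the synthetic dataset (defaults mirror the study)."""

    replicates_per_condition: dict = field(
        default_factory=lambda: {"control": 6, "EoE": 3, "ESCC": 4}
    )
    cells_per_replicate: int = 700
    n_genes: int = 2000
    populations: list = field(default_factory=_default_populations)
    n_modules: int = 4
    module_size: int = 50
    module_latent_sigma: float = 0.8
    module_pop_upreg: float = 3.0
    n_signature_genes: int = 20
    signature_upreg: float = 4.0
    n_cycle_genes: int = 20
    cycle_upreg: float = 4.0
    debris_fraction: float = 0.05
    doublet_fraction: float = 0.05
    nb_dispersion: float = 2.0
    target_depth: float = 2500.0
    seed: int = 0

    def __post_init__(self) -> None:
        for cond in CONDITIONS:
            tot = sum(p.proportions.get(cond, 0.0) for p in self.populations)
            if abs(tot - 1.0) > 1e-6:
                raise ValueError(
                    f"population proportions for {cond!r} sum to {tot:.6f}, not 1"
                )
        for frac in (self.debris_fraction, self.doublet_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("qc noise fractions must lie in [0, 1]")


@dataclass
class SynthResult:
    counts: CountMatrix
    cell_truth: pd.DataFrame  # population, stratum, phase, qc_class per cell
    gene_truth: pd.DataFrame  # module / role per gene
    spec: SynthSpec


# ----------------------------------------------------------------------
def _gene_layout(spec: SynthSpec) -> tuple[np.ndarray, dict]:
    """Gene id vector plus index blocks for each planted role."""
    s_all = default_cycle_genes("S")
    g2m_all = default_cycle_genes("G2M")
    names: list[str] = ["Krt5", "Krtdap", "Trp63", "Krt14", "Krt13", "Krt4"]
    layout: dict = {"s_genes": [], "g2m_genes": [], "signature": {}, "modules": {}}
    for g in s_all[: spec.n_cycle_genes]:
        layout["s_genes"].append(len(names))
        names.append(g)
    for g in g2m_all[: spec.n_cycle_genes]:
        layout["g2m_genes"].append(len(names))
        names.append(g)
    for pop in spec.populations:
        idxs = []
        for j in range(spec.n_signature_genes):
            idxs.append(len(names))
            names.append(f"{pop.name}_sig{j + 1}")
        layout["signature"][pop.name] = idxs
    for k in range(spec.n_modules):
        idxs = []
        for j in range(spec.module_size):
            idxs.append(len(names))
            names.append(f"M{k + 1}_g{j + 1}")
        layout["modules"][f"M{k + 1}"] = idxs
    if len(names) > spec.n_genes:
        raise ValueError(
            f"n_genes={spec.n_genes} too small for planted structure ({len(names)} genes)"
        )
    i = 0
    while len(names) < spec.n_genes:
        i += 1
        names.append(f"gene{i}")
    return np.array(names, dtype=object), layout


def _population_means(spec: SynthSpec, layout: dict, rng: np.random.Generator) -> np.ndarray:
    """Per-population per-gene NB means, scaled to the target depth."""
    n_pops = len(spec.populations)
    base = np.empty(spec.n_genes)
    base[:] = rng.lognormal(mean=np.log(0.5), sigma=1.0, size=spec.n_genes)
    # planted-role genes get moderate, stable baselines
    base[[0, 1, 2, 3, 4, 5]] = 1.0  # overwritten per population below
    # cycle genes rest low outside cycling populations, as real S/G2M markers do
    for idxs in (layout["s_genes"], layout["g2m_genes"]):
        base[idxs] = 0.8
    for idxs in layout["signature"].values():
        base[idxs] = 1.5
    for idxs in layout["modules"].values():
        base[idxs] = 1.0

    mu = np.tile(base, (n_pops, 1))
    panel = {  # Trp63, Krt14 basal; Krt13, Krt4 differentiated
        "basal": (8.0, 15.0, 0.5, 0.3),
        "suprabasal": (2.0, 4.0, 4.0, 2.0),
        "superficial": (0.3, 0.5, 15.0, 10.0),
    }
    # modules are additionally population-specific: the first follows an
    # EoE-enriched suprabasal population, the second an ESCC-enriched basal
    # one, and so on round-robin
    targets = ["SB2", "B5", "SB6", "S1"]
    module_pop = {
        mod: targets[k % len(targets)] for k, mod in enumerate(layout["modules"])
    }
    for i, pop in enumerate(spec.populations):
        mu[i, 0] = pop.krt5_mean
        mu[i, 1] = pop.krtdap_mean
        mu[i, 2:6] = panel[pop.stratum]
        mu[i, layout["signature"][pop.name]] *= spec.signature_upreg
        if pop.cycling == "S":
            mu[i, layout["s_genes"]] *= spec.cycle_upreg
        elif pop.cycling == "G2M":
            mu[i, layout["g2m_genes"]] *= spec.cycle_upreg
        for mod, target in module_pop.items():
            if target == pop.name:
                mu[i, layout["modules"][mod]] *= spec.module_pop_upreg
    # planted trajectory layout: the quiescent basal pool (B1) sits next to the
    # S-phase basal population (B2) in expression space — B1 carries a
    # half-strength copy of B2's signature
    names = [p.name for p in spec.populations]
    if "B1" in names and "B2" in names:
        mu[names.index("B1"), layout["signature"]["B2"]] *= spec.signature_upreg / 2
    # scale every population to the common target depth
    mu *= (spec.target_depth / mu.sum(axis=1))[:, None]
    return mu


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean, dispersion) via the Gamma–Poisson mixture; zero means stay zero."""
    mean = np.asarray(mean, dtype=float)
    lam = np.zeros_like(mean)
    pos = mean > 0
    lam[pos] = rng.gamma(shape=dispersion, scale=mean[pos] / dispersion)
    return rng.poisson(lam)


def generate_dataset(spec: SynthSpec | None = None, seed: int | None = None) -> SynthResult:
    """Draw a full synthetic study: counts, cell truth and gene truth."""
    spec = spec or SynthSpec()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    gene_ids, layout = _gene_layout(spec)
    mu = _population_means(spec, layout, rng)
    pop_names = [p.name for p in spec.populations]
    pop_by_name = {p.name: p for p in spec.populations}
    phase_of = {"none": "G1/G0", "S": "S", "G2M": "G2M"}

    blocks, cell_ids, meta_rows, truth_rows = [], [], [], []
    module_cols = list(layout["modules"].values())

    def draw_block(pop_idx: np.ndarray, depth: float) -> np.ndarray:
        """Vectorized NB draw for a block of cells with latent module factors."""
        m = mu[pop_idx] * depth
        for idxs in module_cols:
            f = rng.lognormal(
                mean=-spec.module_latent_sigma**2 / 2,
                sigma=spec.module_latent_sigma,
                size=len(pop_idx),
            )
            m[:, idxs] *= f[:, None]
        return _nb_draw(rng, m, spec.nb_dispersion)

    cell_no = 0
    for cond in CONDITIONS:
        n_reps = spec.replicates_per_condition[cond]
        props = np.array([pop_by_name[n].proportions[cond] for n in pop_names])
        for rep in range(1, n_reps + 1):
            rep_id = f"{cond}_rep{rep}"
            n = spec.cells_per_replicate
            n_debris = int(round(n * spec.debris_fraction))
            n_doublet = int(round(n * spec.doublet_fraction))
            n_ok = n - n_debris - n_doublet

            ok_pops = rng.choice(len(pop_names), size=n_ok, p=props)
            blocks.append(draw_block(ok_pops, 1.0))
            debris_pops = rng.choice(len(pop_names), size=n_debris, p=props)
            blocks.append(draw_block(debris_pops, 0.02))
            # doublet constituents are drawn at elevated depth so the summed
            # profile exceeds the upper UMI bound (see methods note)
            dbl_a = rng.choice(len(pop_names), size=n_doublet, p=props)
            dbl_b = rng.choice(len(pop_names), size=n_doublet, p=props)
            blocks.append(draw_block(dbl_a, 2.2) + draw_block(dbl_b, 2.2))

            for p in ok_pops:
                cell_no += 1
                cell_ids.append(f"cell{cell_no:06d}")
                meta_rows.append((cond, rep_id))
                truth_rows.append(
                    (pop_names[p], pop_by_name[pop_names[p]].stratum,
                     phase_of[pop_by_name[pop_names[p]].cycling], "ok")
                )
            for p in debris_pops:
                cell_no += 1
                cell_ids.append(f"cell{cell_no:06d}")
                meta_rows.append((cond, rep_id))
                truth_rows.append((pop_names[p], pop_by_name[pop_names[p]].stratum, "NA", "debris"))
            for p in dbl_a:
                cell_no += 1
                cell_ids.append(f"cell{cell_no:06d}")
                meta_rows.append((cond, rep_id))
                truth_rows.append((pop_names[p], pop_by_name[pop_names[p]].stratum, "NA", "doublet"))

    counts = sp.csr_matrix(np.vstack(blocks).astype(np.int64))
    cell_ids_arr = np.array(cell_ids, dtype=object)
    meta = pd.DataFrame(meta_rows, columns=["condition", "replicate"],
                        index=pd.Index(cell_ids_arr, name="cell_id"))
    cm = CountMatrix(counts=counts, cell_ids=cell_ids_arr, gene_ids=gene_ids, cell_meta=meta)

    cell_truth = pd.DataFrame(
        truth_rows, columns=["population", "stratum", "phase", "qc_class"],
        index=pd.Index(cell_ids_arr, name="cell_id"),
    )
    role = np.array(["background"] * spec.n_genes, dtype=object)
    module = np.array([""] * spec.n_genes, dtype=object)
    role[[0, 1, 2, 3, 4, 5]] = "marker"
    role[layout["s_genes"]] = "S"
    role[layout["g2m_genes"]] = "G2M"
    for pop, idxs in layout["signature"].items():
        role[idxs] = f"signature:{pop}"
    for mod, idxs in layout["modules"].items():
        module[idxs] = mod
    gene_truth = pd.DataFrame(
        {"role": role, "module": module}, index=pd.Index(gene_ids, name="gene_id")
    )
    return SynthResult(counts=cm, cell_truth=cell_truth, gene_truth=gene_truth, spec=spec)


# ----------------------------------------------------------------------
def simulate_proportion_counts(
    spec: SynthSpec | None = None,
    cells_per_condition: int = 1500,
    seed: int = 0,
) -> pd.DataFrame:
    """Multinomial per-replicate population counts (no expression draw).

    Emulates the per-replicate composition of a downsampled dataset: each
    condition's cap is split evenly over its replicates and population counts
    are multinomial at the condition's planted proportions.  Used for
    abundance-test power and type-I simulations where drawing full expression
    matrices would be wasteful.
    """
    spec = spec or SynthSpec()
    rng = np.random.default_rng(seed)
    pop_names = [p.name for p in spec.populations]
    rows = []
    index = []
    for cond in CONDITIONS:
        n_reps = spec.replicates_per_condition[cond]
        per_rep = cells_per_condition // n_reps
        props = np.array([p.proportions[cond] for p in spec.populations])
        for rep in range(1, n_reps + 1):
            rows.append(rng.multinomial(per_rep, props))
            index.append((f"{cond}_rep{rep}", cond))
    idx = pd.MultiIndex.from_tuples(index, names=["replicate", "condition"])
    return pd.DataFrame(rows, index=idx, columns=pop_names)


def generate_module_blocks(
    n_cells: int = 200,
    block_sizes: tuple[int, ...] = (50, 50),
    within_corr: float = 0.5,
    n_noise_genes: int = 100,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian block-correlation matrix for module-recovery benchmarks.

    Genes in block *k* share a latent factor giving exact pairwise correlation
    ``within_corr``; noise genes are independent.  Returns (cells × genes
    matrix, block label per gene; -1 marks noise genes).
    """
    rng = np.random.default_rng(seed)
    cols, labels = [], []
    for k, size in enumerate(block_sizes):
        z = rng.standard_normal((n_cells, 1))
        eps = rng.standard_normal((n_cells, size))
        cols.append(np.sqrt(within_corr) * z + np.sqrt(1 - within_corr) * eps)
        labels.extend([k] * size)
    if n_noise_genes:
        cols.append(rng.standard_normal((n_cells, n_noise_genes)))
        labels.extend([-1] * n_noise_genes)
    return np.hstack(cols), np.array(labels)


# ----------------------------------------------------------------------
TUMOR_GROUPS = ("EoE-/ESCC-", "EoE+/ESCC-", "EoE-/ESCC+", "EoE+/ESCC+")
LESION_GRADES = ("none", "IEN", "early ESCC", "invasive ESCC")


def generate_tumor_study(
    group_sizes: dict | None = None,
    effect_factor: float = 0.3,
    tumor_rate: float = 6.0,
    area_shape: float = 2.0,
    area_scale: float = 0.4,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-mouse tumor-study table for the four-arm in vivo design.

    Carcinogen-exposed mice draw tumor counts Poisson(rate) and per-tumor
    areas Gamma(shape, scale) in mm^2; EoE exposure multiplies the rate by
    ``effect_factor`` (< 1 lowers both burden and incidence) and removes
    invasive carcinoma from the lesion-grade distribution.  Carcinogen-free
    groups carry zero tumors.
    """
    group_sizes = group_sizes or {
        "EoE-/ESCC-": 6, "EoE+/ESCC-": 4, "EoE-/ESCC+": 10, "EoE+/ESCC+": 5,
    }
    if any(n < 1 for n in group_sizes.values()):
        raise ValueError("group sizes must be >= 1")
    rng = np.random.default_rng(seed)
    grade_probs = {
        "EoE-/ESCC+": {"IEN": 0.3, "early ESCC": 0.4, "invasive ESCC": 0.3},
        "EoE+/ESCC+": {"IEN": 0.6, "early ESCC": 0.4, "invasive ESCC": 0.0},
    }
    rows = []
    mouse_no = 0
    for group, n in group_sizes.items():
        carcinogen = "ESCC+" in group
        rate = tumor_rate * (effect_factor if "EoE+" in group else 1.0) if carcinogen else 0.0
        for _ in range(n):
            mouse_no += 1
            count = int(rng.poisson(rate)) if carcinogen else 0
            areas = rng.gamma(area_shape, area_scale, size=count) if count else np.array([])
            if count == 0:
                grade = "none"
            else:
                probs = grade_probs[group]
                grade = rng.choice(list(probs), p=list(probs.values()))
            if not carcinogen:
                pct = 0.0
            elif "EoE+" in group:
                pct = float(np.clip(rng.gamma(4.0, 3.0), 0, 100))
            else:
                pct = float(np.clip(rng.gamma(9.0, 3.5), 0, 100))
            rows.append(
                {
                    "mouse_id": f"mouse{mouse_no:03d}",
                    "group": group,
                    "tumor_count": count,
                    "tumor_areas": ";".join(f"{a:.6g}" for a in areas),
                    "lesion_grade": grade,
                    "pct_epithelium_neoplastic": round(pct, 4),
                }
            )
    return pd.DataFrame(rows).set_index("mouse_id")
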