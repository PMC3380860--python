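"""Synthetic inputs emulating the matched-couple dual-cohort study design.

The generator produces every input the analysis consumes: a two-channel
microarray bundle (sample channel ``G``, pooled-reference channel ``R``) over
two leukodystrophy cohorts (eIF2B-mutated, "EIF2B"; other leukodystrophies,
"OL") of matched patient/control couples under two treatments (thapsigargin ER
stress vs ethanol vehicle), replicate-level qPCR Ct tables for fibroblast
validation genes, and a developmental brain isoform panel.  Ground truth about
every implanted effect is carried alongside so recovery can be scored.

Implanted effect classes
------------------------
``null``
    no shift anywhere.
``stress``
    log-shift under thapsigargin, identical in every group (the ER-stress
    signature shared by patients and controls).
``shared_de``
    log-shift in patients of BOTH cohorts (disease-shared, not specific).
``specific_down`` / ``specific_up``
    shift only in EIF2B patients, sized so the expected patient/control ratio
    of corrected log values equals the drawn target rate exactly:
    ``shift = baseline * (rate - 1)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneratorConfig",
    "QpcrPanelConfig",
    "BrainPanelConfig",
    "MicroarrayBundle",
    "CohortSummary",
    "generate_microarray",
    "generate_qpcr_panel",
    "generate_brain_panel",
    "generate_gene_sets",
    "load_cohort_fixture",
    "summarize_cohort",
    "FIBROBLAST_PANEL",
    "SELECTED_GENES_13",
    "ISOFORM_GENES",
    "REFERENCE_GENES",
]

# the ten fibroblast validation genes: nine implanted disease-specific genes
# plus HNRNPF, which narrowly misses the FDR cut and is implanted as a null
FIBROBLAST_PANEL = [
    "HNRNPF",
    "DIAPH3",
    "VDAC3",
    "HNRNPL",
    "MRPL28",
    "HNRNPH1",
    "HCCS",
    "HNRNPC",
    "MRPS26",
    "KIF5B",
]

# brain panel = fibroblast panel + three further HNRNP family members
SELECTED_GENES_13 = FIBROBLAST_PANEL + ["HNRNPU", "HNRNPD", "HNRNPR"]

ISOFORM_GENES = ["PLP", "PLP_DM20", "GFAP_pan", "GFAP_alpha", "GFAP_delta"]
REFERENCE_GENES = ["B2M", "GAPDH", "HPRT"]

# named members of the implanted specific set (six HNRNP genes, two MBNL
# genes, mitochondrial and cytoskeletal validation genes); the remainder of
# the 70 get generic SPEC identifiers
_NAMED_SPECIFIC = [
    "HNRNPH1",
    "HNRNPC",
    "HNRNPD",
    "HNRNPL",
    "HNRNPU",
    "HNRNPR",
    "MBNL1",
    "MBNL2",
    "MRPS26",
    "MRPL28",
    "HCCS",
    "VDAC3",
    "KIF5B",
    "DIAPH3",
]

_MIN_BASELINE = 3.0  # rate-on-corrected-log-value scale needs baselines well above 0


def _rng(seed: int, stream: int) -> np.random.Generator:
    """One independent generator per output table, derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


@dataclass
class GeneratorConfig:
    """Study-design parameters for the synthetic microarray bundle.

    Defaults encode the study scale: 2 cohorts x 10 couples x 2 treatments,
    253 differentially expressed genes of which 70 are eIF2B-specific and 3 of
    those over-expressed (rates 1.06-1.07; under-expression rates below 0.9).
    """

    n_genes: int = 2000
    n_couples_per_cohort: int = 10
    n_stress_genes: int = 150
    n_de_total: int = 253
    n_specific: int = 70
    n_specific_up: int = 3
    n_est_genes: int = 100
    n_loc_genes: int = 50
    baseline_log_mean: float = 8.0
    baseline_log_sd: float = 1.5
    specific_down_rate_interval: tuple[float, float] = (0.66, 0.88)
    specific_up_rate_interval: tuple[float, float] = (1.06, 1.07)
    shared_de_shift: float = -0.6
    stress_shift_sd: float = 0.5
    noise_sd: float = 0.05
    array_effect_sd: float = 0.1
    couple_effect_sd: float = 0.0
    seed: int = 42

    def validate(self) -> None:
        if not (self.n_specific <= self.n_de_total <= self.n_genes):
            raise ValueError(
                "need n_specific <= n_de_total <= n_genes, got "
                f"{self.n_specific}/{self.n_de_total}/{self.n_genes}"
            )
        if self.n_specific_up > self.n_specific:
            raise ValueError("n_specific_up exceeds n_specific")
        lo, hi = self.specific_down_rate_interval
        if not (0 < lo <= hi < 0.9):
            raise ValueError("specific_down_rate_interval must lie strictly below 0.9")
        lo, hi = self.specific_up_rate_interval
        if not (1.05 <= lo <= hi):
            raise ValueError("specific_up_rate_interval must lie at or above 1.05")
        budget = self.n_de_total + self.n_stress_genes + self.n_est_genes + self.n_loc_genes + 1
        if budget > self.n_genes:
            raise ValueError(f"implanted classes need {budget} genes but n_genes={self.n_genes}")


@dataclass
class MicroarrayBundle:
    """Two-channel intensity matrices with design and implanted ground truth."""

    G: pd.DataFrame  # gene x array sample-channel intensities (>0)
    R: pd.DataFrame  # gene x array pooled-reference intensities (>0)
    design: pd.DataFrame  # one row per array
    truth: pd.DataFrame  # one row per gene
    couple_folds: pd.DataFrame | None = None  # gene x couple fold jitter (shared w/ qPCR)

    def write(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.G.to_csv(out / "intensities_G.tsv", sep="\t", index_label="gene_id")
        self.R.to_csv(out / "intensities_R.tsv", sep="\t", index_label="gene_id")
        self.design.to_csv(out / "design.tsv", sep="\t", index=False)
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)


def _build_design(n_couples: int) -> pd.DataFrame:
    rows = []
    for cohort, tag in (("EIF2B", "E"), ("OL", "O")):
        for c in range(1, n_couples + 1):
            couple_id = f"{tag}{c:02d}"
            for role, rtag in (("patient", "P"), ("control", "C")):
                subject_id = f"{couple_id}{rtag}"
                for treatment, ttag in (("thapsigargin", "T"), ("vehicle", "V")):
                    rows.append(
                        {
                            "sample_id": f"{subject_id}_{ttag}",
                            "subject_id": subject_id,
                            "role": role,
                            "cohort": cohort,
                            "couple_id": couple_id,
                            "treatment": treatment,
                        }
                    )
    return pd.DataFrame(rows)


def _gene_table(cfg: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    n_down = cfg.n_specific - cfg.n_specific_up
    named = _NAMED_SPECIFIC[: min(len(_NAMED_SPECIFIC), n_down)]
    spec_ids = named + [f"SPEC{i:03d}" for i in range(len(named) + 1, cfg.n_specific + 1)]
    n_shared = cfg.n_de_total - cfg.n_specific
    shared_ids = [f"SHRD{i:03d}" for i in range(1, n_shared + 1)]
    stress_ids = [f"STRS{i:03d}" for i in range(1, cfg.n_stress_genes + 1)]
    est_ids = [f"EST{i:04d}" for i in range(1, cfg.n_est_genes + 1)]
    loc_ids = [f"LOC{i:06d}" for i in range(1, cfg.n_loc_genes + 1)]
    n_null = cfg.n_genes - len(spec_ids) - n_shared - cfg.n_stress_genes - len(est_ids) - len(loc_ids)
    null_ids = ["HNRNPF"] + [f"GENE{i:04d}" for i in range(1, n_null)]

    gene_id = spec_ids + shared_ids + stress_ids + null_ids + est_ids + loc_ids
    klass = (
        ["specific_down"] * n_down
        + ["specific_up"] * cfg.n_specific_up
        + ["shared_de"] * n_shared
        + ["stress"] * cfg.n_stress_genes
        + ["null"] * len(null_ids)
        + ["null"] * (len(est_ids) + len(loc_ids))
    )
    annotation = (
        ["characterized"] * (cfg.n_genes - len(est_ids) - len(loc_ids))
        + ["EST"] * len(est_ids)
        + ["LOC"] * len(loc_ids)
    )
    t = pd.DataFrame({"gene_id": gene_id, "class": klass, "annotation": annotation})

    baseline = np.clip(
        rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, cfg.n_genes), _MIN_BASELINE, None
    )
    t["baseline"] = baseline

    rate = np.ones(cfg.n_genes)
    is_down = (t["class"] == "specific_down").to_numpy()
    is_up = (t["class"] == "specific_up").to_numpy()
    rate[is_down] = rng.uniform(*cfg.specific_down_rate_interval, is_down.sum())
    rate[is_up] = rng.uniform(*cfg.specific_up_rate_interval, is_up.sum())

    shift = np.zeros(cfg.n_genes)
    shift[is_down | is_up] = baseline[is_down | is_up] * (rate[is_down | is_up] - 1.0)
    is_shared = (t["class"] == "shared_de").to_numpy()
    shift[is_shared] = cfg.shared_de_shift
    rate[is_shared] = (baseline[is_shared] + cfg.shared_de_shift) / baseline[is_shared]

    stress_shift = np.zeros(cfg.n_genes)
    is_stress = (t["class"] == "stress").to_numpy()
    stress_shift[is_stress] = rng.normal(0.0, cfg.stress_shift_sd, is_stress.sum())

    t["implanted_shift"] = shift
    t["implanted_rate"] = rate
    t["stress_shift"] = stress_shift
    return t


def generate_microarray(config: GeneratorConfig | None = None) -> MicroarrayBundle:
    """Simulate the paired sample/reference intensity matrices.

    Log intensities follow ``baseline_g + array_effect_a + status shift +
    stress shift + noise``; the reference channel shares the per-slide array
    effect (both channels hybridize on the same slide) and the per-gene
    baseline of the pooled control reference, with independent noise.
    """
    cfg = config or GeneratorConfig()
    cfg.validate()
    rng = _rng(cfg.seed, 0)

    design = _build_design(cfg.n_couples_per_cohort)
    truth = _gene_table(cfg, rng)
    n_genes, n_arrays = cfg.n_genes, len(design)

    baseline = truth["baseline"].to_numpy()[:, None]
    array_effect = rng.normal(0.0, cfg.array_effect_sd, n_arrays)[None, :]

    is_patient = (design["role"] == "patient").to_numpy()[None, :]
    is_eif2b = (design["cohort"] == "EIF2B").to_numpy()[None, :]
    is_thaps = (design["treatment"] == "thapsigargin").to_numpy()[None, :]

    klass = truth["class"].to_numpy()[:, None]
    shift = truth["implanted_shift"].to_numpy()[:, None]
    affected = np.where(
        np.isin(klass, ["specific_down", "specific_up"]),
        is_patient & is_eif2b,
        np.where(klass == "shared_de", is_patient, False),
    )
    L = baseline + array_effect + shift * affected
    L = L + truth["stress_shift"].to_numpy()[:, None] * is_thaps

    couple_folds = None
    if cfg.couple_effect_sd > 0:
        couples = design["couple_id"].unique()
        jitter = rng.normal(0.0, cfg.couple_effect_sd, (n_genes, len(couples)))
        implanted = np.isin(truth["class"], ["specific_down", "specific_up", "shared_de"])
        jitter[~implanted] = 0.0
        couple_folds = pd.DataFrame(jitter, index=truth["gene_id"], columns=couples)
        col_of = {c: i for i, c in enumerate(couples)}
        jit_cols = np.array([col_of[c] for c in design["couple_id"]])
        L = L + jitter[:, jit_cols] * (affected & True)

    L = L + rng.normal(0.0, cfg.noise_sd, (n_genes, n_arrays))
    LR = baseline + array_effect + rng.normal(0.0, cfg.noise_sd, (n_genes, n_arrays))

    cols = design["sample_id"].to_numpy()
    G = pd.DataFrame(np.exp(L), index=truth["gene_id"].to_numpy(), columns=cols)
    R = pd.DataFrame(np.exp(LR), index=truth["gene_id"].to_numpy(), columns=cols)
    G.index.name = R.index.name = "gene_id"
    return MicroarrayBundle(G=G, R=R, design=design, truth=truth, couple_folds=couple_folds)


# ---------------------------------------------------------------------------
# qPCR fibroblast panel


@dataclass
class QpcrPanelConfig:
    """Replicate-level Ct simulation for the fibroblast validation panel."""

    n_couples_per_cohort: int = 10
    ct_noise_sd: float = 0.2  # cycles, per replicate
    ct0_range: tuple[float, float] = (20.0, 28.0)  # per-gene baseline Ct window
    reference_ct: float = 18.0  # B2M
    censor_ct: float = 40.0
    n_rt: int = 2
    n_duplicates: int = 2
    seed: int = 42


def generate_qpcr_panel(
    truth: pd.DataFrame,
    gene_ids: Sequence[str],
    config: QpcrPanelConfig | None = None,
    couple_folds: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Long-format Ct records for the fibroblast couples.

    Each (sample, gene) gets ``n_rt x n_duplicates`` replicate rows.  The Ct
    model is ``ct0_g - log2(relative expression) + noise``; a patient's
    relative expression is the implanted fold of the gene in the subject's
    cohort (specific genes act only in EIF2B patients, shared genes in
    patients of both cohorts), so at zero noise
    ``Ct_patient - Ct_control = -log2(fold)``.
    """
    cfg = config or QpcrPanelConfig()
    rng = _rng(cfg.seed, 1)
    tr = truth.set_index("gene_id")
    unknown = [g for g in gene_ids if g not in tr.index]
    if unknown:
        raise KeyError(f"gene ids not present in truth table: {unknown}")

    design = _build_design(cfg.n_couples_per_cohort)
    subjects = design.drop_duplicates("subject_id")

    ct0 = {g: rng.uniform(*cfg.ct0_range) for g in gene_ids}
    ct0["B2M"] = cfg.reference_ct

    rows = []
    for _, s in subjects.iterrows():
        for treatment in ("thapsigargin", "vehicle"):
            sample_id = f"{s.subject_id}_{'T' if treatment == 'thapsigargin' else 'V'}"
            for gene in list(gene_ids) + ["B2M"]:
                fold = 1.0
                if gene != "B2M" and s.role == "patient":
                    k = tr.at[gene, "class"]
                    if k in ("specific_down", "specific_up") and s.cohort == "EIF2B":
                        fold = float(tr.at[gene, "implanted_rate"])
                    elif k == "shared_de":
                        fold = float(tr.at[gene, "implanted_rate"])
                    if fold != 1.0 and couple_folds is not None and gene in couple_folds.index:
                        fold *= math.exp(float(couple_folds.at[gene, s.couple_id]))
                base = ct0[gene] - (math.log2(fold) if fold > 0 else 0.0)
                for rt in range(1, cfg.n_rt + 1):
                    for rep in range(1, cfg.n_duplicates + 1):
                        ct = base + rng.normal(0.0, cfg.ct_noise_sd)
                        rows.append(
                            {
                                "sample_id": sample_id,
                                "subject_id": s.subject_id,
                                "cohort": s.cohort,
                                "couple_id": s.couple_id,
                                "role": s.role,
                                "treatment": treatment,
                                "gene": gene,
                                "rt_batch": rt,
                                "replicate": rep,
                                "ct": min(ct, cfg.censor_ct),
                                "censored": ct >= cfg.censor_ct,
                            }
                        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# brain developmental isoform panel


@dataclass
class BrainPanelConfig:
    """Developmental brain panel: PLP/DM20 and GFAP isoforms plus 13 genes.

    Group sizes default to the autopsy roster scale (foetus 2 mutated / 6
    control, child 7 / 5, adult 2 / 3).  ``gfap_delta_fold`` implants the
    stage-specific GFAPdelta over-expression (2x foetus, 4.5x child, 7x
    adult); PLP-family transcripts are censored in control foetal brains and
    reduced ``plp_postnatal_reduction``-fold in mutated postnatal brains; the
    mutated foetal PLP+DM20/PLP ratio is elevated ``foetal_dm20_ratio_increase``-fold.
    """

    group_sizes: dict = field(
        default_factory=lambda: {
            "foetus": {"mutated": 2, "control": 6},
            "child": {"mutated": 7, "control": 5},
            "adult": {"mutated": 2, "control": 3},
        }
    )
    gfap_delta_fold: dict = field(
        default_factory=lambda: {"foetus": 2.0, "child": 4.5, "adult": 7.0}
    )
    plp_postnatal_reduction: float = 0.3
    foetal_dm20_ratio_increase: float = 2.0
    selected_gene_foetal_fold: float = 1.5
    selected_gene_postnatal_fold: float = 0.6
    ct_noise_sd: float = 0.2
    censor_ct: float = 40.0
    n_rt: int = 2
    n_duplicates: int = 2

    def validate(self) -> None:
        for d in (self.gfap_delta_fold,):
            if any(v <= 0 for v in d.values()):
                raise ValueError("folds must be positive")
        for v in (
            self.plp_postnatal_reduction,
            self.foetal_dm20_ratio_increase,
            self.selected_gene_foetal_fold,
            self.selected_gene_postnatal_fold,
        ):
            if v <= 0:
                raise ValueError("folds must be positive")
        for stage, sizes in self.group_sizes.items():
            if min(sizes.values()) < 1:
                raise ValueError(f"group sizes at stage {stage} must be >= 1")


# control relative expressions vs B2M (2^-dCt scale); GFAP peaks in childhood,
# PLP-family transcripts are undetectable in control foetal brain
_CONTROL_EXPR = {
    "GFAP_pan": {"foetus": 0.05, "child": 1.0, "adult": 0.4},
    "GFAP_alpha": {"foetus": 0.045, "child": 0.9, "adult": 0.36},
    "GFAP_delta": {"foetus": 0.005, "child": 0.1, "adult": 0.04},
    "PLP": {"foetus": None, "child": 1.0, "adult": 0.8},
    "PLP_DM20": {"foetus": None, "child": 1.25, "adult": 1.0},
}
_FOETAL_MUTATED_PLP = 0.01  # low but detectable in affected foetal brain
_REFERENCE_CT = {"B2M": 18.0, "GAPDH": 20.0, "HPRT": 24.0}
_SELECTED_CONTROL_EXPR = 0.5


def generate_brain_panel(config: BrainPanelConfig | None = None, seed: int = 42) -> pd.DataFrame:
    """Long-format Ct table across developmental stages and disease groups."""
    cfg = config or BrainPanelConfig()
    cfg.validate()
    rng = _rng(seed, 2)

    def expr_for(gene: str, stage: str, group: str) -> float | None:
        if gene in _REFERENCE_CT:
            return 1.0
        if gene in _CONTROL_EXPR:
            base = _CONTROL_EXPR[gene][stage]
            if group == "control":
                return base
            if gene == "GFAP_delta":
                return base * cfg.gfap_delta_fold[stage]
            if gene in ("GFAP_pan", "GFAP_alpha"):
                return base
            # PLP family, mutated
            if stage == "foetus":
                if gene == "PLP":
                    return _FOETAL_MUTATED_PLP
                postnatal_ratio = _CONTROL_EXPR["PLP_DM20"]["child"] / _CONTROL_EXPR["PLP"]["child"]
                return _FOETAL_MUTATED_PLP * postnatal_ratio * cfg.foetal_dm20_ratio_increase
            return base * cfg.plp_postnatal_reduction
        # 13 selected genes
        base = _SELECTED_CONTROL_EXPR
        if group == "control":
            return base
        if stage == "foetus":
            return base * cfg.selected_gene_foetal_fold
        return base * cfg.selected_gene_postnatal_fold

    genes = ISOFORM_GENES + SELECTED_GENES_13 + REFERENCE_GENES
    rows = []
    for stage in ("foetus", "child", "adult"):
        for group in ("mutated", "control"):
            for i in range(1, cfg.group_sizes[stage][group] + 1):
                sample_id = f"{stage[:2].upper()}_{'M' if group == 'mutated' else 'C'}{i}"
                for gene in genes:
                    expr = expr_for(gene, stage, group)
                    if gene in _REFERENCE_CT:
                        base_ct = _REFERENCE_CT[gene]
                    elif expr is None:
                        base_ct = None  # undetectable
                    else:
                        base_ct = _REFERENCE_CT["B2M"] - math.log2(expr)
                    for rt in range(1, cfg.n_rt + 1):
                        for rep in range(1, cfg.n_duplicates + 1):
                            if base_ct is None:
                                ct, censored = cfg.censor_ct, True
                            else:
                                ct = base_ct + rng.normal(0.0, cfg.ct_noise_sd)
                                censored = ct >= cfg.censor_ct
                                ct = min(ct, cfg.censor_ct)
                            rows.append(
                                {
                                    "sample_id": sample_id,
                                    "group": group,
                                    "stage": stage,
                                    "gene": gene,
                                    "rt_batch": rt,
                                    "replicate": rep,
                                    "ct": ct,
                                    "censored": censored,
                                }
                            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# gene-set annotation (GMT-style) for the enrichment stage


def generate_gene_sets(truth: pd.DataFrame, seed: int = 42, n_random: int = 8) -> dict[str, set]:
    """Fabricate a small category annotation over the simulated universe.

    Two categories are seeded with implanted specific genes (an mRNA-processing
    programme and a mitochondrial one) so over-representation is recoverable;
    the rest are random draws from the characterized universe.
    """
    rng = _rng(seed, 3)
    universe = truth.loc[truth["annotation"] == "characterized", "gene_id"].tolist()
    specific = truth.loc[truth["class"].isin(["specific_down", "specific_up"]), "gene_id"].tolist()
    other = [g for g in universe if g not in set(specific)]

    n_spec = len(specific)
    sets: dict[str, set] = {}
    sets["MRNA_PROCESSING"] = set(
        rng.choice(specific, min(40, max(1, int(0.57 * n_spec))), replace=False)
    ) | set(rng.choice(other, min(60, len(other)), replace=False))
    sets["MITOCHONDRIAL_METABOLISM"] = set(
        rng.choice(specific, min(12, max(1, int(0.17 * n_spec))), replace=False)
    ) | set(rng.choice(other, min(90, len(other)), replace=False))
    for i in range(1, n_random + 1):
        size = int(rng.integers(50, min(200, len(universe))))
        sets[f"RANDOM_PROCESS_{i:02d}"] = set(rng.choice(universe, size, replace=False))
    return sets


def write_gmt(sets: dict[str, set], path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "synthetic"] + sorted(members)) + "\n")


# ---------------------------------------------------------------------------
# cohort fixture (study metadata table, transcribed)


def _parse_age(value: str) -> float:
    """Parse an age/duration string ('2.3 y', '6 m', '10 d', 'At birth', 'NA') to years."""
    v = value.strip().replace(",", ".")
    if v in ("NA", ""):
        return math.nan
    if v.lower() == "at birth":
        return 0.0
    num, unit = v.split()
    x = float(num)
    if unit.startswith("y"):
        return x
    if unit.startswith("m"):
        return x / 12.0
    if unit.startswith("d"):
        return x / 365.0
    raise ValueError(f"unparseable age value: {value!r}")


def load_cohort_fixture() -> pd.DataFrame:
    """Packaged cohort metadata: 20 patients (10 eIF2B-related disorder, 10 OL).

    The spec's conventions: '6 m' -> 0.5 y, '10 d' -> 10/365 y, 'At birth' -> 0,
    'NA' -> missing.  A ``group`` column separates the eIF2B cohort ('ERD')
    from the other-leukodystrophy cohort ('OL').
    """
    with resources.files("specifex.data").joinpath("cohort_table.tsv").open() as fh:
        raw = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
    expected = {"patient_id", "disease_type", "onset_age", "duration", "gender", "biopsy_age"}
    if set(raw.columns) != expected:
        raise ValueError(f"malformed cohort fixture: columns {list(raw.columns)}")
    out = raw.copy()
    for col in ("onset_age", "duration", "biopsy_age"):
        out[col] = raw[col].map(_parse_age)
    out["group"] = np.where(out["disease_type"] == "ERD", "ERD", "OL")
    return out


@dataclass
class CohortSummary:
    mean: float
    sd: float
    min: float
    max: float
    n: int


def summarize_cohort(table: pd.DataFrame, group: str, field: str) -> CohortSummary:
    """Mean, sample SD (n-1), min, max over non-missing values of a group."""
    vals = table.loc[table["group"] == group, field].dropna()
    if len(vals) < 2:
        raise ValueError(f"need >=2 non-missing values for {group}/{field}, got {len(vals)}")
    return CohortSummary(
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=1)),
        min=float(vals.min()),
        max=float(vals.max()),
        n=int(len(vals)),
    )
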