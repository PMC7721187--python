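"""File I/O, allele harmonisation, run configuration and the pipeline driver.

Tabular inputs and outputs are TSV with a header row.  Weight tables follow
the usual GWAS summary layout (variant_id, effect_allele, other_allele and
either a fetal/maternal weight pair or a single weight column); dosage files
are individuals x variants, optionally accompanied by a variant-info table
for allele harmonisation, or ingested from a VCF's DS format field.

``run_pipeline`` chains simulate -> z-score -> score -> classify -> associate
-> deviation-test for a list of cohorts, writes every stage's output under
one directory, and records a machine-readable manifest (seed, config hash,
counts at each filter) so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import association as assoc_mod
from . import deviation as dev_mod
from . import phenotype as phen_mod
from . import scores as scores_mod
from . import simulate as sim_mod
from .simulate import ContaminationSpec, DuoCohort, SnpPanel

__all__ = [
    "read_weights",
    "read_dosages",
    "read_vcf_dosages",
    "harmonise_alleles",
    "RunConfig",
    "CohortConfig",
    "run_pipeline",
]

log = logging.getLogger("duopgs")

_VALID_ALLELES = {"A", "C", "G", "T"}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_AMBIGUOUS = {frozenset(("A", "T")), frozenset(("C", "G"))}


# ---------------------------------------------------------------------------
# weight tables

def read_weights(path: str | Path) -> SnpPanel:
    """Read a score weight table and orient weights to the score-raising
    allele.

    Accepts either ``w_fetal``/``w_maternal`` columns (duo score tables) or a
    single ``weight`` column (e.g. maternal fasting-glucose or blood-pressure
    scores), which is copied into both weight slots.  Rows whose fetal (or
    single) weight is negative are flipped: alleles swapped, weights negated
    and, when present, the frequency complemented.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"variant_id", "effect_allele", "other_allele"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"weight table missing columns: {sorted(missing)}")
    if "weight" in df.columns:
        df = df.assign(w_fetal=df["weight"], w_maternal=df["weight"])
    if not {"w_fetal", "w_maternal"}.issubset(df.columns):
        raise ValueError(
            "weight table needs w_fetal and w_maternal columns, or a single "
            "weight column"
        )
    dupes = df["variant_id"][df["variant_id"].duplicated()]
    if len(dupes):
        raise ValueError(
            f"duplicate variant_id in weight table: {sorted(dupes.unique())}"
        )
    for col in ("effect_allele", "other_allele"):
        bad = ~df[col].isin(_VALID_ALLELES)
        if bad.any():
            raise ValueError(
                f"unknown alleles in {col}: {sorted(df.loc[bad, col].unique())}"
            )
    flip = (df["w_fetal"] < 0).to_numpy()
    if flip.any():
        log.info("orienting %d variants to the score-raising allele", flip.sum())
        ea = df["effect_allele"].to_numpy(dtype=object)
        oa = df["other_allele"].to_numpy(dtype=object)
        ea[flip], oa[flip] = oa[flip].copy(), ea[flip].copy()
        df["effect_allele"], df["other_allele"] = ea, oa
        df.loc[flip, ["w_fetal", "w_maternal"]] *= -1
        if "freq" in df.columns:
            df.loc[flip, "freq"] = 1 - df.loc[flip, "freq"]
    if "freq" not in df.columns:
        df["freq"] = 0.5  # placeholder; frequency is re-estimated from dosages
    return SnpPanel.from_frame(df)


# ---------------------------------------------------------------------------
# dosage ingestion and allele harmonisation

def harmonise_alleles(
    file_ea: str, file_oa: str, panel_ea: str, panel_oa: str
) -> str | None:
    """Resolve allele orientation between a dosage source and the panel.

    Returns ``"keep"``, ``"swap"`` (dosage becomes 2 - g) or ``None`` when
    the variant must be dropped (strand-ambiguous A/T / C/G pairs, or
    irreconcilable alleles).
    """
    if frozenset((panel_ea, panel_oa)) in _AMBIGUOUS:
        return None
    pair = (file_ea, file_oa)
    comp = (_COMPLEMENT.get(file_ea), _COMPLEMENT.get(file_oa))
    if pair == (panel_ea, panel_oa) or comp == (panel_ea, panel_oa):
        return "keep"
    if pair == (panel_oa, panel_ea) or comp == (panel_oa, panel_ea):
        return "swap"
    return None


def _align(
    matrix: np.ndarray,
    variant_ids: list[str],
    variant_info: pd.DataFrame | None,
    panel: SnpPanel,
) -> tuple[np.ndarray, dict[str, int]]:
    """Reorder columns to panel order, harmonising alleles where possible."""
    col_of = {v: j for j, v in enumerate(variant_ids)}
    n = matrix.shape[0]
    out = np.full((n, panel.n_snps), np.nan)
    info_of = {}
    if variant_info is not None:
        info_of = {
            r.variant_id: (r.effect_allele, r.other_allele)
            for r in variant_info.itertuples()
        }
    counts = {"kept": 0, "swapped": 0, "dropped_ambiguous": 0,
              "dropped_mismatch": 0, "missing": 0}
    for i in range(panel.n_snps):
        vid = panel.variant_id[i]
        j = col_of.get(vid)
        if j is None:
            counts["missing"] += 1
            continue
        if vid in info_of:
            action = harmonise_alleles(
                *info_of[vid], panel.effect_allele[i], panel.other_allele[i]
            )
            if action is None:
                ambiguous = (
                    frozenset((panel.effect_allele[i], panel.other_allele[i]))
                    in _AMBIGUOUS
                )
                counts["dropped_ambiguous" if ambiguous else "dropped_mismatch"] += 1
                continue
        else:
            action = "keep"
        if action == "swap":
            out[:, i] = 2.0 - matrix[:, j]
            counts["swapped"] += 1
        else:
            out[:, i] = matrix[:, j]
            counts["kept"] += 1
    found = panel.n_snps - counts["missing"]
    if found < 0.5 * panel.n_snps:
        raise ValueError(
            f"only {found}/{panel.n_snps} panel SNPs found in dosage source"
        )
    if counts["dropped_ambiguous"]:
        log.warning(
            "dropped %d strand-ambiguous SNPs", counts["dropped_ambiguous"]
        )
    if counts["dropped_mismatch"]:
        log.warning(
            "dropped %d allele-mismatched SNPs", counts["dropped_mismatch"]
        )
    return out, counts


def read_dosages(
    path: str | Path,
    panel: SnpPanel,
    variant_info: str | Path | pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Read an individuals x variants dosage TSV aligned to ``panel``.

    ``variant_info`` (TSV or frame with variant_id/effect_allele/other_allele)
    enables allele harmonisation; without it, columns matching panel variant
    IDs are taken at face value.  Returns the aligned frame (index =
    individual IDs, columns = panel variant IDs; unresolvable variants NaN)
    plus harmonisation counts.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if "individual_id" not in df.columns:
        raise ValueError("dosage TSV needs an individual_id column")
    ids = df["individual_id"].astype(str)
    mat = df.drop(columns="individual_id")
    if isinstance(variant_info, (str, Path)):
        variant_info = pd.read_csv(variant_info, sep="\t", comment="#")
    aligned, counts = _align(
        mat.to_numpy(dtype=float), list(mat.columns), variant_info, panel
    )
    out = pd.DataFrame(aligned, index=ids, columns=list(panel.variant_id))
    return out, counts


def read_vcf_dosages(
    path: str | Path, panel: SnpPanel
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Ingest dosages from a VCF: the DS format field when present, else
    hard-genotype allele counts.  Alleles are harmonised against the panel."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, vids, eas, oas = [], [], [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            continue
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        ds = rec.format("DS")
        if ds is not None:
            dose = np.asarray(ds, dtype=float).reshape(len(samples))
        else:
            gt = np.asarray(rec.genotype.array())[:, :2]
            dose = np.where((gt < 0).any(axis=1), np.nan, (gt > 0).sum(axis=1)).astype(
                float
            )
        rows.append(dose)
        vids.append(vid)
        eas.append(rec.ALT[0])
        oas.append(rec.REF)
    if not rows:
        raise ValueError("no usable biallelic records in VCF")
    matrix = np.column_stack(rows)
    info = pd.DataFrame(
        {"variant_id": vids, "effect_allele": eas, "other_allele": oas}
    )
    aligned, counts = _align(matrix, vids, info, panel)
    out = pd.DataFrame(aligned, index=samples, columns=list(panel.variant_id))
    return out, counts


# ---------------------------------------------------------------------------
# run configuration and pipeline driver

@dataclass
class CohortConfig:
    """One cohort: either simulated (n set) or read from files."""

    cohort_id: str
    n: int | None = None
    fetal_dosages: str | None = None
    maternal_dosages: str | None = None
    phenotypes: str | None = None
    variant_info: str | None = None
    contamination_mode: str = "none"
    contamination_fraction: float = 0.0
    shift_sd: float = 0.0
    rare_freq: float = 0.0
    rare_beta: float = 0.0

    def contamination(self) -> ContaminationSpec:
        return ContaminationSpec(
            mode=self.contamination_mode,
            fraction=self.contamination_fraction,
            shift_sd=self.shift_sd,
            rare_freq=self.rare_freq,
            rare_beta=self.rare_beta,
        )


@dataclass
class RunConfig:
    """Everything a pipeline run depends on; hashable for provenance."""

    out_dir: str
    seed: int = 0
    cohorts: list[CohortConfig] = field(default_factory=list)
    panel_path: str | None = None
    reference_path: str | None = None
    n_snps: int = 200
    gs_variance: float = 0.07
    maternal_fetal_corr: float = 0.0
    z_method: str = "within"  # "within" | "external"
    scheme: str = "threshold_1_28"
    control_scheme: str = "complement"
    bin_width: float = 10.0
    bin_anchor: str = "lower"
    n_sims: int = 1000
    deviation_members: tuple[str, ...] = ("fetal", "maternal")

    def __post_init__(self) -> None:
        self.cohorts = [
            c if isinstance(c, CohortConfig) else CohortConfig(**c)
            for c in self.cohorts
        ]
        if not self.cohorts:
            raise ValueError("config lists no cohorts")
        for c in self.cohorts:
            if c.n is None:
                for attr in ("fetal_dosages", "phenotypes"):
                    if getattr(c, attr) is None:
                        raise ValueError(
                            f"cohort {c.cohort_id}: set n (simulate) or provide "
                            f"{attr}"
                        )
        if self.z_method not in ("within", "external"):
            raise ValueError("z_method must be 'within' or 'external'")
        if self.z_method == "external" and not self.reference_path:
            raise ValueError("external z-scores require reference_path")
        for p_attr in ("panel_path", "reference_path"):
            p = getattr(self, p_attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{p_attr}: {p}")
        for c in self.cohorts:
            for attr in ("fetal_dosages", "maternal_dosages", "phenotypes",
                         "variant_info"):
                p = getattr(c, attr)
                if p is not None and not Path(p).exists():
                    raise FileNotFoundError(f"cohort {c.cohort_id} {attr}: {p}")

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["deviation_members"] = list(self.deviation_members)
        return d

    def config_hash(self) -> str:
        # out_dir is where results land, not what they depend on
        payload = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def _write_tsv(df: pd.DataFrame, path: Path, stamp: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {stamp}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute every stage for every cohort; returns the manifest dict.

    All randomness derives from ``config.seed`` via named substreams, so a
    rerun with an identical config is byte-identical.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = f"duopgs seed={config.seed} config={config.config_hash()}"
    root_ss = np.random.SeedSequence(config.seed)
    manifest: dict[str, Any] = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "cohorts": {},
        "outputs": [],
    }

    last = [time.perf_counter(), "start"]

    def _stage(name):
        now = time.perf_counter()
        log.info("stage %s done in %.2fs; starting %s", last[1], now - last[0], name)
        last[0], last[1] = now, name

    # --- panel -------------------------------------------------------------
    _stage("panel")
    if config.panel_path:
        panel = read_weights(config.panel_path)
    else:
        panel = sim_mod.generate_panel(
            config.n_snps,
            effect_sd=sim_mod.effect_sd_for_variance(
                config.gs_variance, config.n_snps
            ),
            maternal_fetal_corr=config.maternal_fetal_corr,
            seed=root_ss.spawn(1)[0],
        )
    panel_df = panel.to_frame()
    _write_tsv(panel_df, out / "panel.tsv", stamp)
    manifest["outputs"].append("panel.tsv")
    manifest["n_snps"] = panel.n_snps

    reference = None
    if config.reference_path:
        reference = pd.read_csv(config.reference_path, sep="\t", comment="#")

    per_cohort_assoc: dict[tuple[str, str], list[assoc_mod.AssocResult]] = {}
    per_cohort_dev: dict[str, list[list[dev_mod.DeviationResult]]] = {
        m: [] for m in config.deviation_members
    }
    dev_sizes: dict[str, list[int]] = {m: [] for m in config.deviation_members}
    bins = dev_mod.BinSpec(config.bin_width, config.bin_anchor)

    for k, cc in enumerate(config.cohorts):
        ss = np.random.SeedSequence(config.seed, spawn_key=(k + 1,))
        counts: dict[str, Any] = {}
        # --- simulate or load ---------------------------------------------
        _stage(f"{cc.cohort_id}: cohort")
        if cc.n is not None:
            cohort = sim_mod.generate_cohort(
                panel,
                cc.n,
                seed=ss,
                cohort_id=cc.cohort_id,
                contamination=cc.contamination(),
            )
            harmonisation = None
        else:
            fet, h_f = read_dosages(
                cc.fetal_dosages, panel, variant_info=cc.variant_info
            )
            g_mat = None
            harmonisation = {"fetal": h_f}
            if cc.maternal_dosages:
                mat, h_m = read_dosages(
                    cc.maternal_dosages, panel, variant_info=cc.variant_info
                )
                g_mat = mat.to_numpy()
                harmonisation["maternal"] = h_m
            phen = pd.read_csv(cc.phenotypes, sep="\t", comment="#")
            cohort = DuoCohort(
                cohort_id=cc.cohort_id,
                g_fetal=fet.to_numpy(),
                g_maternal=g_mat,
                phenotypes=phen,
            )
        counts["n_in"] = cohort.n
        sim_mod.write_cohort(cohort, out / cc.cohort_id, panel=panel)
        # --- term filter and z-scores --------------------------------------
        _stage(f"{cc.cohort_id}: z-scores")
        term_mask = (
            cohort.phenotypes["gestational_age_wk"] >= phen_mod.TERM_GA_WEEKS
        ).to_numpy()
        counts["n_term"] = int(term_mask.sum())
        counts["n_excluded_preterm"] = int((~term_mask).sum())
        phen_term = cohort.phenotypes[term_mask].reset_index(drop=True)
        g_fet = cohort.g_fetal[term_mask]
        g_mat = None if cohort.g_maternal is None else cohort.g_maternal[term_mask]
        cohort_term = DuoCohort(
            cohort_id=cc.cohort_id,
            g_fetal=g_fet,
            g_maternal=g_mat,
            phenotypes=phen_term,
        )
        if config.z_method == "within":
            z = phen_mod.zscore_within_cohort(phen_term)
        else:
            z = phen_mod.zscore_external(phen_term, reference)
        _write_tsv(z.to_frame(), out / f"{cc.cohort_id}.zscores.tsv", stamp)
        # --- scores ---------------------------------------------------------
        _stage(f"{cc.cohort_id}: scores")
        ids = phen_term["individual_id"].to_numpy(dtype=object)
        fetal_scores = scores_mod.to_deciles(
            scores_mod.compute_gs(g_fet, panel, "fetal", individual_id=ids)
        )
        score_frames = [fetal_scores.to_frame()]
        maternal_scores = None
        if g_mat is not None:
            maternal_scores = scores_mod.to_deciles(
                scores_mod.compute_gs(g_mat, panel, "maternal", individual_id=ids)
            )
            score_frames.append(maternal_scores.to_frame())
        _write_tsv(
            pd.concat(score_frames, ignore_index=True),
            out / f"{cc.cohort_id}.scores.tsv",
            stamp,
        )
        # --- classify --------------------------------------------------------
        _stage(f"{cc.cohort_id}: classify")
        labels = phen_mod.classify(
            z, scheme=config.scheme, control_scheme=config.control_scheme
        )
        _write_tsv(labels.to_frame(), out / f"{cc.cohort_id}.labels.tsv", stamp)
        counts["n_sga"] = int(np.sum(labels.label == "SGA"))
        counts["n_lga"] = int(np.sum(labels.label == "LGA"))
        # --- association ------------------------------------------------------
        _stage(f"{cc.cohort_id}: association")
        for outcome in ("SGA", "LGA"):
            res = assoc_mod.fit_logistic(
                labels,
                fetal_scores,
                outcome,
                phenotypes=phen_term,
                cohort_id=cc.cohort_id,
            )
            per_cohort_assoc.setdefault(("fetal", outcome), []).append(res)
            if maternal_scores is not None:
                res_m = assoc_mod.fit_logistic(
                    labels,
                    maternal_scores,
                    outcome,
                    phenotypes=phen_term,
                    cohort_id=cc.cohort_id,
                )
                per_cohort_assoc.setdefault(("maternal", outcome), []).append(res_m)
        # --- deviation test ---------------------------------------------------
        if cohort_term.g_maternal is not None:
            _stage(f"{cc.cohort_id}: deviation test")
            # conditional per-SNP models need complete dosages; restrict to
            # columns without missingness (harmonisation drops leave NaN)
            ok = ~np.isnan(cohort_term.g_fetal).any(axis=0)
            ok &= ~np.isnan(cohort_term.g_maternal).any(axis=0)
            cohort_dev = DuoCohort(
                cohort_id=cc.cohort_id,
                g_fetal=cohort_term.g_fetal[:, ok],
                g_maternal=cohort_term.g_maternal[:, ok],
                phenotypes=phen_term,
            )
            for member in config.deviation_members:
                results = dev_mod.run_deviation_test(
                    cohort_dev,
                    z,
                    member=member,
                    bins=bins,
                    n_sims=config.n_sims,
                    seed=np.random.SeedSequence(
                        config.seed,
                        spawn_key=(k + 1, {"fetal": 101, "maternal": 102}[member]),
                    ),
                )
                per_cohort_dev[member].append(results)
                dev_sizes[member].append(cohort_term.n)
        if harmonisation:
            counts["harmonisation"] = harmonisation
        manifest["cohorts"][cc.cohort_id] = counts

    # --- meta-analysis ------------------------------------------------------
    _stage("meta-analysis")
    assoc_rows = [r for rs in per_cohort_assoc.values() for r in rs]
    metas = [
        assoc_mod.meta_fixed(rs)
        for rs in per_cohort_assoc.values()
        if len(rs) >= 2
    ]
    _write_tsv(
        assoc_mod.results_to_frame(assoc_rows, metas), out / "assoc.tsv", stamp
    )
    manifest["outputs"].append("assoc.tsv")
    dev_frames = []
    for member, per_cohort in per_cohort_dev.items():
        for results in per_cohort:
            df = dev_mod.deviation_to_frame(results)
            df.insert(0, "member", member)
            dev_frames.append(df)
        if len(per_cohort) >= 2:
            combined = dev_mod.meta_p(per_cohort, dev_sizes[member])
            combined.insert(0, "member", member)
            combined["cohort_id"] = "POOLED"
            dev_frames.append(combined)
    if dev_frames:
        _write_tsv(
            pd.concat(dev_frames, ignore_index=True),
            out / "deviation.tsv",
            stamp,
        )
        manifest["outputs"].append("deviation.tsv")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
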