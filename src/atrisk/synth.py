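"""Synthetic-data generator for all three analysis arms.

Emulates the statistical structure of the study inputs — methylation
beta matrices from two cohorts of three participant groups, per-subject
cytometry event tables with tetramer-positive spike-ins, and an
antibody-array MFI matrix with clinical covariates — with planted,
configurable group effects whose ground truth is returned alongside
the data. Every generated dataset is byte-identical under a fixed
seed.

Default settings follow the study design: serology group sizes
172/97/62 (control / at-risk / early RA), tetramer sub-cohort sizes
30/24/17, covariate distributions matching the baseline table
(age ~57.8/58.5/51.8 y, ~65-68% female, 34-53% ever-smokers), a
41-antigen panel with 27 citrullinated and 14 native antigens, and
methylation effects expressed as differences of mean beta.

The beta noise model is logit-normal per locus: values stay in (0, 1)
and the logit-scale SD is chosen by the delta method so that the
beta-scale SD approximately equals ``beta_noise_sd``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from ._stats import stable_child_seed
from .landscape import MARKERS, inverse_transform
from .methylome import BetaMatrix
from .serology import SerumArray
from .types import GROUPS

log = logging.getLogger("atrisk")


def _default_cluster_spec() -> list:
    # three well-separated helper-like archetypes in transformed space
    # marker order: CD45RA, CD38, CCR4, CCR6, CXCR3, CCR7
    return [
        ((2.5, 0.5, 0.5, 0.5, 0.5, 2.5), 0.5),  # naive-like
        ((0.5, 1.0, 0.5, 0.5, 2.5, 1.0), 0.3),  # Th1-like
        ((0.5, 1.0, 2.5, 2.5, 0.5, 1.0), 0.2),  # Th17-like
    ]


def _default_tmr_enrichment() -> dict:
    # expected Tmr+ frequency per million CD4, per antigen per group;
    # cit-CILP expanded in the at-risk group, influenza flat
    return {
        "cit-aggrecan": {"ctrl": 1.5, "at_risk": 2.5, "early_ra": 2.5},
        "cit-CILP": {"ctrl": 1.5, "at_risk": 6.0, "early_ra": 4.0},
        "cit-vimentin/fibrinogen": {"ctrl": 1.5, "at_risk": 2.5, "early_ra": 2.5},
        "cit-enolase": {"ctrl": 1.5, "at_risk": 2.0, "early_ra": 2.0},
        "influenza": {"ctrl": 20.0, "at_risk": 20.0, "early_ra": 20.0},
    }


def _default_antigen_effects() -> dict:
    # multiplicative MFI shifts per antigen summing group and participant
    # group; the early-RA shifts exceed the at-risk shifts throughout
    return {
        "cit-clusterin": {"at_risk": 1.6, "early_ra": 2.5},
        "cit-fibrinogen": {"at_risk": 1.4, "early_ra": 2.5},
        "cit-histone-H4": {"at_risk": 1.5, "early_ra": 2.5},
        "cit-fillagrin": {"at_risk": 1.3, "early_ra": 2.0},
        "CILP": {"early_ra": 2.0},
    }


#: Table-1 covariate distributions per group: age mean/SD, fraction
#: female, fraction ever-smokers, fraction carrying *04:01.
COVARIATE_DISTRIBUTIONS = {
    "ctrl": {"age": (57.8, 12.6), "female": 0.680, "smoking": 0.343, "hla_0401": 33 / 172},
    "at_risk": {"age": (58.5, 12.6), "female": 0.649, "smoking": 0.361, "hla_0401": 26 / 97},
    "early_ra": {"age": (51.8, 12.9), "female": 0.661, "smoking": 0.532, "hla_0401": 24 / 62},
}


@dataclass
class SynthConfig:
    """All knobs of the generator; defaults emulate the study design."""

    # methylation arm
    n_per_group_per_cohort: int = 10
    n_probes: int = 2000
    n_planted_dml: int = 50
    delta_beta_effect: float = 0.3
    replication_rate: float = 1.0
    beta_noise_sd: float = 0.05
    affected_group: str = "at_risk"
    cell_type: str = "Tmem"
    # cytometry arm
    n_subjects_flow: dict = field(
        default_factory=lambda: {"ctrl": 30, "at_risk": 24, "early_ra": 17})
    n_events_per_subject: int = 2000
    cluster_spec: list = field(default_factory=_default_cluster_spec)
    cluster_sd: float = 0.2
    tmr_enrichment: dict = field(default_factory=_default_tmr_enrichment)
    tmr_phenotype_weights: dict = field(default_factory=dict)
    cd4_pre_mean: float = 30000.0
    # serology arm
    n_subjects_serum: dict = field(
        default_factory=lambda: {"ctrl": 172, "at_risk": 97, "early_ra": 62})
    antigen_effects: dict = field(default_factory=_default_antigen_effects)
    mfi_log_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.n_subjects_flow, int):
            self.n_subjects_flow = {g: self.n_subjects_flow for g in GROUPS}
        if isinstance(self.n_subjects_serum, int):
            self.n_subjects_serum = {g: self.n_subjects_serum for g in GROUPS}
        if self.n_probes <= 0 or self.n_per_group_per_cohort <= 0:
            raise ValueError("counts must be positive")
        if self.n_planted_dml > self.n_probes:
            raise ValueError("n_planted_dml exceeds n_probes")
        if not 0 <= self.replication_rate <= 1:
            raise ValueError("replication_rate must lie in [0, 1]")
        if self.cluster_spec:
            props = [p for _, p in self.cluster_spec]
            if abs(sum(props) - 1) > 1e-9:
                raise ValueError("cluster_spec proportions must sum to 1")
            for mean, _ in self.cluster_spec:
                if len(mean) != len(MARKERS):
                    raise ValueError("cluster_spec means must have one entry per marker")
        if self.affected_group not in GROUPS:
            raise ValueError(f"affected_group must be one of {GROUPS}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        return cfg

    def to_yaml(self, path) -> None:
        import yaml

        d = self.to_dict()
        d["cluster_spec"] = [[list(m), p] for m, p in d["cluster_spec"]]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# methylation arm
# ---------------------------------------------------------------------------

def make_beta_matrix(cfg: SynthConfig) -> tuple[BetaMatrix, pd.DataFrame]:
    """Two-cohort, three-group beta matrix with planted DML.

    Baseline probe means are uniform on (0.15, 0.95 - effect); sample
    values are logit-normal around the (possibly shifted) mean.
    Planted loci are shifted by ``delta_beta_effect`` in the affected
    group; all planted loci are active in cohort 1 and a
    ``replication_rate`` fraction of them also in cohort 2. The truth
    table lists each planted probe with its cohorts and effect.
    """
    rng = np.random.default_rng(stable_child_seed(cfg.seed, "beta"))
    n = cfg.n_probes
    delta = cfg.delta_beta_effect
    probe_ids = [f"cg{i:07d}" for i in range(n)]
    base_mean = rng.uniform(0.15, max(0.16, 0.95 - max(delta, 0.0)), size=n)

    planted = rng.choice(n, size=cfg.n_planted_dml, replace=False) if cfg.n_planted_dml else np.array([], dtype=int)
    n_shared = int(round(cfg.replication_rate * len(planted)))
    shared = set(planted[:n_shared])

    samples, meta_rows = [], []
    columns = {}
    for cohort in (1, 2):
        for group in GROUPS:
            for i in range(cfg.n_per_group_per_cohort):
                sid = f"c{cohort}_{group}_{i:02d}"
                mu = base_mean.copy()
                if group == cfg.affected_group and delta != 0 and len(planted):
                    active = planted if cohort == 1 else np.array(sorted(shared), dtype=int)
                    mu[active] = mu[active] + delta
                mu = np.clip(mu, 1e-3, 1 - 1e-3)
                sd_logit = cfg.beta_noise_sd / (mu * (1 - mu))
                vals = expit(rng.normal(logit(mu), sd_logit))
                columns[sid] = vals
                samples.append(sid)
                meta_rows.append((sid, group, cohort, cfg.cell_type, sid))

    values = pd.DataFrame(columns, index=probe_ids)
    meta = pd.DataFrame(meta_rows, columns=["sample", "group", "cohort", "cell_type", "subject"]).set_index("sample")
    truth = pd.DataFrame({
        "probe": [probe_ids[i] for i in planted],
        "cohorts": [[1, 2] if i in shared else [1] for i in planted],
        "group": cfg.affected_group,
        "delta_beta": delta,
    })
    return BetaMatrix(values, meta), truth


# ---------------------------------------------------------------------------
# cytometry arm
# ---------------------------------------------------------------------------

def make_event_tables(cfg: SynthConfig) -> tuple[list[pd.DataFrame], pd.DataFrame]:
    """Per-subject raw event tables with Tmr+ spike-ins and truth labels.

    Total-CD4 events are drawn from the configured Gaussian mixture in
    transformed space and mapped back to raw intensities; Tmr+ events
    are drawn per antigen at Poisson counts implied by the per-million
    enrichment frequencies and appended to the subject's table exactly
    as enriched events are concatenated to the total-CD4 files in the
    assay layout. Each table carries ``true_component`` (ground truth,
    stripped by the CSV writer into a sidecar) and ``cd4_pre``.

    Returns the tables and a per-subject/antigen count summary
    (``tmr_events``, ``cd4_pre``) usable by the tetramer arm.
    """
    if not cfg.cluster_spec:
        raise ValueError("cluster_spec must be non-empty")
    if cfg.n_events_per_subject <= 0:
        raise ValueError("n_events_per_subject must be positive")
    rng = np.random.default_rng(stable_child_seed(cfg.seed, "events"))
    means = np.array([m for m, _ in cfg.cluster_spec], dtype=float)
    props = np.array([p for _, p in cfg.cluster_spec], dtype=float)

    def draw(n_events: int, weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        comp = rng.choice(len(weights), size=n_events, p=weights)
        T = rng.normal(means[comp], cfg.cluster_sd)
        return comp, T

    tables, count_rows = [], []
    for group in GROUPS:
        for i in range(int(cfg.n_subjects_flow[group])):
            subject = f"{group}_s{i:02d}"
            comp, T = draw(cfg.n_events_per_subject, props)
            frames = [pd.DataFrame({
                "subject": subject, "group": group, "tmr": False, "antigen": "",
                "true_component": comp,
                **{mk: inverse_transform(T[:, j]) for j, mk in enumerate(MARKERS)},
            })]
            cd4_pre = int(rng.poisson(cfg.cd4_pre_mean))
            for antigen, per_group in cfg.tmr_enrichment.items():
                freq = float(per_group.get(group, 0.0))
                lam = freq * 100 * cd4_pre / 1e6
                n_tmr = int(rng.poisson(lam)) if lam > 0 else 0
                count_rows.append((subject, group, antigen, n_tmr, cd4_pre))
                if n_tmr == 0:
                    continue
                w = np.asarray(cfg.tmr_phenotype_weights.get(antigen, props), dtype=float)
                w = w / w.sum()
                tcomp, tT = draw(n_tmr, w)
                frames.append(pd.DataFrame({
                    "subject": subject, "group": group, "tmr": True, "antigen": antigen,
                    "true_component": tcomp,
                    **{mk: inverse_transform(tT[:, j]) for j, mk in enumerate(MARKERS)},
                }))
            table = pd.concat(frames, ignore_index=True)
            table["cd4_pre"] = cd4_pre
            tables.append(table)
    counts = pd.DataFrame(count_rows, columns=["subject", "group", "antigen", "tmr_events", "cd4_pre"])
    return tables, counts


# ---------------------------------------------------------------------------
# serology arm
# ---------------------------------------------------------------------------

def default_antigen_panel() -> pd.DataFrame:
    """The 41-antigen panel: 27 citrullinated, 14 native.

    Summing-group membership is a synthetic placeholder built from the
    group names reported for the assay (cit-clusterin, cit-fibrinogen,
    cit-fillagrin, cit-histone-H4, and ten CILP peptides); the real
    peptide-level assignments are part of the assay design and are
    user-replaceable.
    """
    rows = []

    def add(prefix, n, cit, grp):
        for i in range(n):
            rows.append((f"{prefix}_{i + 1}", cit, grp))

    add("cit-clusterin", 3, True, "cit-clusterin")
    add("cit-fibrinogen", 4, True, "cit-fibrinogen")
    add("cit-fillagrin", 2, True, "cit-fillagrin")
    add("cit-histone-H4", 2, True, "cit-histone-H4")
    add("cit-CILP", 5, True, "CILP")
    add("CILP", 5, False, "CILP")
    add("cit-misc", 11, True, "")
    add("native-misc", 9, False, "")
    panel = pd.DataFrame(rows, columns=["antigen", "citrullinated", "antigen_group"]).set_index("antigen")
    assert len(panel) == 41 and int(panel["citrullinated"].sum()) == 27
    return panel


def make_serum_array(cfg: SynthConfig, panel: pd.DataFrame | None = None) -> tuple[SerumArray, dict]:
    """Antibody-array MFI matrix with covariates and planted shifts.

    Control MFI is log-normal per antigen (antigen-specific baselines);
    subjects of a participant group have every antigen of a summing
    group multiplied by the configured effect. Covariates are drawn
    from the baseline-table distributions. The truth dict maps each
    participant group to the antigen groups shifted in it.
    """
    rng = np.random.default_rng(stable_child_seed(cfg.seed, "serum"))
    panel = default_antigen_panel() if panel is None else panel
    antigens = list(panel.index)
    baseline = rng.normal(np.log(500.0), 0.3, size=len(antigens))

    subj_rows, mfi_rows, index = [], [], []
    for group in GROUPS:
        dist = COVARIATE_DISTRIBUTIONS[group]
        for i in range(int(cfg.n_subjects_serum[group])):
            sid = f"{group}_p{i:03d}"
            index.append(sid)
            subj_rows.append((
                sid, group,
                float(rng.normal(*dist["age"])),
                int(rng.random() < dist["female"]),
                int(rng.random() < dist["smoking"]),
                int(rng.random() < dist["hla_0401"]),
            ))
            shift = np.ones(len(antigens))
            for j, a in enumerate(antigens):
                grp = panel.loc[a, "antigen_group"]
                eff = cfg.antigen_effects.get(grp, {}).get(group, 1.0) if grp else 1.0
                shift[j] = eff
            mfi_rows.append(np.exp(rng.normal(baseline, cfg.mfi_log_sd)) * shift)

    mfi = pd.DataFrame(mfi_rows, index=index, columns=antigens)
    cov = pd.DataFrame(
        subj_rows, columns=["subject", "group", "age", "sex", "smoking_ever", "hla_0401"]
    ).set_index("subject")
    truth = {
        "affected": {
            g: sorted(grp for grp, eff in cfg.antigen_effects.items() if eff.get(g, 1.0) != 1.0)
            for g in GROUPS
        }
    }
    return SerumArray(mfi, panel, cov), truth


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_all(cfg: SynthConfig, out_dir) -> dict:
    """Generate and write every input kind plus truth sidecars.

    Produces TSV/CSV files for the three arms, JSON truth sidecars and
    the YAML config; returns the path map.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    beta, beta_truth = make_beta_matrix(cfg)
    beta.values.to_csv(out / "beta_values.tsv", sep="\t")
    beta.sample_meta.to_csv(out / "beta_samples.tsv", sep="\t")
    (out / "beta_truth.json").write_text(json.dumps(beta_truth.to_dict(orient="records"), indent=1))
    paths["beta"] = [out / "beta_values.tsv", out / "beta_samples.tsv"]

    tables, counts = make_event_tables(cfg)
    flow_dir = out / "flow"
    flow_dir.mkdir(exist_ok=True)
    truth_components = {}
    for table in tables:
        subject = table["subject"].iloc[0]
        truth_components[subject] = table["true_component"].tolist()
        table.drop(columns=["true_component"]).to_csv(flow_dir / f"{subject}.csv", index=False)
    counts.to_csv(out / "tmr_counts.csv", index=False)
    (out / "flow_truth.json").write_text(json.dumps(truth_components))
    paths["flow"] = [flow_dir, out / "tmr_counts.csv"]

    arr, serum_truth = make_serum_array(cfg)
    arr.mfi.to_csv(out / "serum_mfi.csv")
    arr.antigen_meta.to_csv(out / "serum_antigens.csv")
    arr.covariates.to_csv(out / "serum_covariates.csv")
    (out / "serum_truth.json").write_text(json.dumps(serum_truth, indent=1))
    paths["serum"] = [out / "serum_mfi.csv", out / "serum_antigens.csv", out / "serum_covariates.csv"]

    cfg.to_yaml(out / "synth_config.yaml")
    paths["config"] = [out / "synth_config.yaml"]
    return paths
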