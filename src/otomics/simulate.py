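"""Synthetic multi-omics cohort generator with ground truth.

Emulates the statistical structure the subtyping pipeline assumes, so that
every downstream stage can be exercised and its recovery quantified without
external data:

* log-scale mRNA expression with additive per-subtype signature blocks,
  a normal-brain profile, and tumours contaminated by normal tissue as a
  convex mixture with the normal mean profile;
* negative-binomial miRNA read counts with subtype-specific means and
  per-sample sequencing depths;
* logit-normal methylation beta values with a planted CIMP island offset,
  subtype signature CpGs, and the two single-CpG event probes (MYC exon 3
  hypomethylation, mir34b/c promoter hypermethylation);
* gain/normal/loss segments covering every chromosome arm, with 1p/19q
  loss in the co-deleted subtypes, enriched arm losses and focal MYC gain /
  MAX (14q) loss in the aggressive OPC-like subtype;
* exponential survival with subtype-specific hazards, independent
  censoring, and a radiotherapy benefit confined to the aggressive subtype.

Defaults reproduce the structure of the discovery cohort: five subtypes
C1..C5 sized (47, 25, 36, 17, 16) of which C1/C4/C5 are 1p/19q co-deleted
(the O1/O2/O3 groups), 9 normal controls and 29 contaminated tumours, and
the aggressive subtype's MYC-event probabilities (gain 0.09, MAX loss 0.35,
exon 3 hypomethylation 0.20, mir34b/c hypermethylation 0.28).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .types import ConfigError, GNLTable, OmicsMatrix, load_arm_table

__all__ = ["CohortConfig", "SyntheticCohort", "generate_cohort", "planted_event_rates"]

EVENT_NAMES = ("myc_gain", "max_loss", "myc_hypometh", "mir34_hypermeth")

_MYC_REGION = ("8", 128_748_315, 128_753_680)


def _logit(p):
    return np.log(p / (1.0 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort. ``seed`` fixes everything."""

    # cohort composition
    subtype_names: tuple[str, ...] = ("C1", "C2", "C3", "C4", "C5")
    n_per_subtype: tuple[int, ...] = (47, 25, 36, 17, 16)
    codel_subtypes: tuple[str, ...] = ("C1", "C4", "C5")
    aggressive_subtype: str = "C1"  # OPC-like group
    idhwt_subtypes: tuple[str, ...] = ("C2",)
    n_normal_controls: int = 9
    n_contaminated: int = 29
    contamination_w: float = 0.8

    # mRNA
    n_genes: int = 2000
    signature_size: int = 40
    signature_effect: float = 2.0  # log2 mean shift
    noise_sd: float = 1.0
    n_arm_probes_1p: int = 50
    n_arm_probes_19q: int = 50
    codel_shift: float = -0.3
    normal_signature_size: int = 60
    normal_signature_effect: float = 3.0
    n_myc_targets: int = 30
    myc_target_shift: float = 1.0

    # miRNA
    n_mirnas: int = 400
    mirna_signature_size: int = 20
    mirna_signature_log2fc: float = 1.5
    mirna_dispersion: float = 0.3
    depth_log_sd: float = 0.3

    # methylation
    n_cpgs: int = 1000
    island_fraction: float = 0.5
    meth_signature_size: int = 40
    meth_signature_effect: float = 1.5  # logit scale
    cimp_offset: float = 1.5  # logit scale
    meth_noise_sd: float = 0.5
    na_cell_fraction: float = 0.01

    # MYC events; None -> aggressive subtype gets the cohort-level
    # frequencies, all other subtypes a 0.02 background rate
    event_probs: Mapping[str, Mapping[str, float]] | None = None
    exclusivity_mode: str = "independent"  # or "exclusive"
    aggressive_event_probs: tuple[float, float, float, float] = (0.09, 0.35, 0.20, 0.28)
    background_event_prob: float = 0.02

    # additional arm events (probability of loss/gain per subtype);
    # None -> defaults: aggressive 9p/4/18q losses, IDHwt 7 gain + 10 loss,
    # C3-like 7 gain + 11p loss
    arm_loss_probs: Mapping[str, Mapping[str, float]] | None = None
    arm_gain_probs: Mapping[str, Mapping[str, float]] | None = None

    # survival (months)
    hazards: Mapping[str, float] | None = None
    aggressive_hazard: float = 0.012
    default_hazard: float = 0.006
    censor_rate: float = 0.004
    followup_cap: float = 180.0
    rt_fraction: float = 0.5
    rt_hazard_ratio: Mapping[str, float] | None = None
    aggressive_rt_hazard_ratio: float = 0.4

    # missingness per omic (probability a sample is absent from that omic)
    missing_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"mrna": 0.0, "mirna": 0.02, "methylation": 0.35}
    )

    # When set, per-feature baselines (gene expression, miRNA abundance,
    # CpG methylation) are drawn from this separate seed, so cohorts built
    # with different ``seed`` but one ``baseline_seed`` share them —
    # emulating the cross-dataset conservation of gene-level baseline
    # expression that cross-cohort centroid matching relies on.
    baseline_seed: int | None = None

    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_per_subtype) != len(self.subtype_names):
            raise ConfigError("n_per_subtype and subtype_names lengths differ")
        if any(n < 0 for n in self.n_per_subtype):
            raise ConfigError("n_per_subtype entries must be >= 0")
        if not set(self.codel_subtypes) <= set(self.subtype_names):
            raise ConfigError("codel_subtypes must be subtype names")
        if self.aggressive_subtype not in self.subtype_names:
            raise ConfigError("aggressive_subtype must be a subtype name")
        if not 0.0 <= self.contamination_w <= 1.0:
            raise ConfigError("contamination_w must be in [0,1]")
        for v in self.missing_fraction.values():
            if not 0.0 <= v <= 1.0:
                raise ConfigError("missing_fraction entries must be in [0,1]")
        for probs in self.resolved_event_probs().values():
            for v in probs.values():
                if not 0.0 <= v <= 1.0:
                    raise ConfigError("event probabilities must be in [0,1]")
        if self.exclusivity_mode not in ("independent", "exclusive"):
            raise ConfigError("exclusivity_mode must be independent or exclusive")

    def resolved_event_probs(self) -> dict[str, dict[str, float]]:
        if self.event_probs is not None:
            return {s: dict(p) for s, p in self.event_probs.items()}
        out = {}
        for s in self.subtype_names:
            if s == self.aggressive_subtype:
                out[s] = dict(zip(EVENT_NAMES, self.aggressive_event_probs))
            else:
                out[s] = {e: self.background_event_prob for e in EVENT_NAMES}
        return out

    def resolved_arm_probs(self) -> tuple[dict, dict]:
        losses = {s: {} for s in self.subtype_names}
        gains = {s: {} for s in self.subtype_names}
        if self.arm_loss_probs is None:
            losses[self.aggressive_subtype] = {"9p": 0.25, "4": 0.15, "18q": 0.20}
            for s in self.idhwt_subtypes:
                losses[s] = {"10": 0.7}
            if "C3" in self.subtype_names:
                losses["C3"] = {"11p": 0.41}
        else:
            for s, p in self.arm_loss_probs.items():
                losses[s] = dict(p)
        if self.arm_gain_probs is None:
            for s in self.idhwt_subtypes:
                gains[s] = {"7": 0.7}
            if "C3" in self.subtype_names:
                gains["C3"] = {"7": 0.54}
        else:
            for s, p in self.arm_gain_probs.items():
                gains[s] = dict(p)
        return losses, gains

    def resolved_hazards(self) -> dict[str, float]:
        if self.hazards is not None:
            return dict(self.hazards)
        out = {}
        for s in self.subtype_names:
            if s == self.aggressive_subtype:
                out[s] = self.aggressive_hazard
            elif s in self.idhwt_subtypes:
                out[s] = 0.02
            elif s == "C3":
                out[s] = 0.008
            else:
                out[s] = self.default_hazard
        return out

    def resolved_rt_ratio(self) -> dict[str, float]:
        if self.rt_hazard_ratio is not None:
            return dict(self.rt_hazard_ratio)
        return {
            s: (self.aggressive_rt_hazard_ratio if s == self.aggressive_subtype else 1.0)
            for s in self.subtype_names
        }


@dataclass
class SyntheticCohort:
    """Generated matrices plus the ground truth they were built from."""

    mrna: OmicsMatrix
    mirna_counts: pd.DataFrame
    methylation: OmicsMatrix
    gnl: GNLTable
    annot: pd.DataFrame
    truth: pd.DataFrame
    signature_genes: dict[str, list[str]]
    myc_target_genes: list[str]
    normal_signature_genes: list[str]
    config: CohortConfig


def _gene_layout(cfg: CohortConfig):
    """Deterministic gene block layout (shared across cohorts/seeds)."""
    n_sub = len(cfg.subtype_names)
    need = (
        n_sub * cfg.signature_size
        + cfg.n_myc_targets
        + cfg.normal_signature_size
        + cfg.n_arm_probes_1p
        + cfg.n_arm_probes_19q
    )
    if cfg.n_genes < need:
        raise ConfigError(f"n_genes={cfg.n_genes} < {need} required by gene blocks")
    ids = [f"G{i + 1:05d}" for i in range(cfg.n_genes)]
    pos = 0
    sig = {}
    for s in cfg.subtype_names:
        sig[s] = ids[pos : pos + cfg.signature_size]
        pos += cfg.signature_size
    myc_targets = ids[pos : pos + cfg.n_myc_targets]
    pos += cfg.n_myc_targets
    normal_sig = ids[pos : pos + cfg.normal_signature_size]
    pos += cfg.normal_signature_size
    probes_1p = ids[pos : pos + cfg.n_arm_probes_1p]
    pos += cfg.n_arm_probes_1p
    probes_19q = ids[pos : pos + cfg.n_arm_probes_19q]
    pos += cfg.n_arm_probes_19q
    return ids, sig, myc_targets, normal_sig, probes_1p, probes_19q


def _gene_annot(cfg, ids, probes_1p, probes_19q) -> pd.DataFrame:
    arms = load_arm_table()
    other = arms[~arms["arm"].isin(["1p", "19q"])].reset_index(drop=True)
    rows = {}
    for arm_name, probes in (("1p", probes_1p), ("19q", probes_19q)):
        a = arms.set_index("arm").loc[arm_name]
        span = (a["end"] - a["start"]) // max(len(probes) + 1, 1)
        for i, g in enumerate(probes):
            s = int(a["start"] + (i + 1) * span)
            rows[g] = (str(a["chrom"]), arm_name, s, s + 1000)
    rest = [g for g in ids if g not in rows]
    for i, g in enumerate(rest):
        a = other.iloc[i % len(other)]
        offset = (i // len(other)) + 1
        span = (a["end"] - a["start"]) // 2000
        s = int(a["start"] + offset * max(span, 2000))
        s = min(s, int(a["end"]) - 1001)
        rows[g] = (str(a["chrom"]), a["arm"], s, s + 1000)
    annot = pd.DataFrame.from_dict(
        rows, orient="index", columns=["chrom", "arm", "start", "end"]
    )
    return annot.loc[ids]


def _draw_events(cfg: CohortConfig, subtypes: list[str], rng) -> pd.DataFrame:
    probs = cfg.resolved_event_probs()
    rows = []
    for s in subtypes:
        p = probs[s]
        if cfg.exclusivity_mode == "exclusive":
            pv = np.array([p[e] for e in EVENT_NAMES])
            if pv.sum() > 1:
                raise ConfigError("exclusive mode needs event probs summing <= 1")
            draw = rng.multinomial(1, np.append(pv, 1.0 - pv.sum()))
            rows.append(dict(zip(EVENT_NAMES, draw[:-1].astype(bool))))
        else:
            rows.append({e: bool(rng.random() < p[e]) for e in EVENT_NAMES})
    return pd.DataFrame(rows)


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a full multi-omics cohort plus ground truth from one seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    base_rng = (
        np.random.default_rng(cfg.baseline_seed)
        if cfg.baseline_seed is not None
        else rng
    )

    # ----- sample universe -----------------------------------------------
    subtypes: list[str] = []
    for name, n in zip(cfg.subtype_names, cfg.n_per_subtype):
        subtypes.extend([name] * n)
    n_clean = len(subtypes)
    contam_subtypes = [
        cfg.subtype_names[i % len(cfg.subtype_names)] for i in range(cfg.n_contaminated)
    ]
    subtypes.extend(contam_subtypes)
    n_tum = len(subtypes)
    tumour_ids = [f"T{i + 1:03d}" for i in range(n_tum)]
    normal_ids = [f"N{i + 1:02d}" for i in range(cfg.n_normal_controls)]
    samples = tumour_ids + normal_ids
    contam_w = np.r_[
        np.zeros(n_clean), np.full(cfg.n_contaminated, cfg.contamination_w),
        np.zeros(cfg.n_normal_controls),
    ]
    is_normal = np.r_[np.zeros(n_tum, bool), np.ones(cfg.n_normal_controls, bool)]
    codel = np.array(
        [s in cfg.codel_subtypes for s in subtypes] + [False] * cfg.n_normal_controls
    )
    all_subtypes = subtypes + ["NORMAL"] * cfg.n_normal_controls

    # ----- MYC events ------------------------------------------------------
    events = _draw_events(cfg, subtypes, rng)
    events.index = tumour_ids
    events = events.reindex(samples)
    events.loc[normal_ids] = False
    any_event = events[list(EVENT_NAMES)].any(axis=1)

    # ----- mRNA ------------------------------------------------------------
    ids, sig, myc_targets, normal_sig, probes_1p, probes_19q = _gene_layout(cfg)
    annot = _gene_annot(cfg, ids, probes_1p, probes_19q)
    baseline = base_rng.normal(7.0, 1.0, size=cfg.n_genes)
    gene_pos = {g: i for i, g in enumerate(ids)}
    codel_gene_idx = [gene_pos[g] for g in probes_1p + probes_19q]
    normal_mean = baseline.copy()
    normal_mean[[gene_pos[g] for g in normal_sig]] += cfg.normal_signature_effect

    mean = np.tile(baseline[:, None], (1, len(samples)))
    for j, s in enumerate(all_subtypes):
        if s == "NORMAL":
            mean[:, j] = normal_mean
            continue
        mean[[gene_pos[g] for g in sig[s]], j] += cfg.signature_effect
        if codel[j]:
            mean[codel_gene_idx, j] += cfg.codel_shift
        if any_event.iloc[j]:
            mean[[gene_pos[g] for g in myc_targets], j] += cfg.myc_target_shift
        w = contam_w[j]
        if w > 0:
            mean[:, j] = (1 - w) * mean[:, j] + w * normal_mean
    mrna_vals = mean + rng.normal(0.0, cfg.noise_sd, size=mean.shape)
    mrna = OmicsMatrix(
        pd.DataFrame(mrna_vals, index=ids, columns=samples), "mrna", annot
    )

    # ----- miRNA -----------------------------------------------------------
    mir_ids = [f"mir{i + 1:04d}" for i in range(cfg.n_mirnas)]
    mir_base = base_rng.normal(6.0, 2.5, size=cfg.n_mirnas).clip(min=0.0)
    mir_sig = {}
    pos = 0
    for s in cfg.subtype_names:
        mir_sig[s] = list(range(pos, pos + cfg.mirna_signature_size))
        pos += cfg.mirna_signature_size
    if pos > cfg.n_mirnas:
        raise ConfigError("n_mirnas too small for miRNA signature blocks")
    depth = rng.lognormal(0.0, cfg.depth_log_sd, size=len(samples))
    log2mu = np.tile(mir_base[:, None], (1, len(samples)))
    for j, s in enumerate(all_subtypes):
        if s == "NORMAL":
            continue
        shift = cfg.mirna_signature_log2fc * (1.0 - contam_w[j])
        log2mu[mir_sig[s], j] += shift
    mu = (2.0**log2mu) * depth[None, :]
    r = 1.0 / cfg.mirna_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    mirna_counts = pd.DataFrame(counts, index=mir_ids, columns=samples, dtype=int)

    # ----- methylation -----------------------------------------------------
    special = ["cg00163372", "cg22879515", "cg21881253", "cg13767940", "cg23211240"]
    n_rest = cfg.n_cpgs - len(special)
    if n_rest <= cfg.meth_signature_size * len(cfg.subtype_names):
        raise ConfigError("n_cpgs too small")
    cpg_ids = special + [f"cgS{i + 1:06d}" for i in range(n_rest)]
    n_island = int(round(cfg.island_fraction * n_rest))
    island_flag = np.r_[
        np.array([False, True, True, True, True]),  # mir34 probes sit in an island
        np.ones(n_island, bool), np.zeros(n_rest - n_island, bool),
    ]
    base_logit = np.empty(cfg.n_cpgs)
    base_logit[0] = 1.4  # MYC exon 3 probe: methylated at baseline
    base_logit[1:5] = -1.6  # mir34b/c island probes: unmethylated at baseline
    base_logit[5 : 5 + n_island] = base_rng.normal(-2.0, 0.5, size=n_island)
    base_logit[5 + n_island :] = base_rng.normal(0.0, 1.2, size=n_rest - n_island)

    meth_sig = {}
    pos = 5 + n_island  # subtype CpG signatures on non-island probes
    for s in cfg.subtype_names:
        meth_sig[s] = list(range(pos, pos + cfg.meth_signature_size))
        pos += cfg.meth_signature_size
        if pos > cfg.n_cpgs:
            raise ConfigError("n_cpgs too small for methylation signatures")

    cimp_subtypes = set(cfg.codel_subtypes) | (
        {"C3"} if "C3" in cfg.subtype_names else set()
    )
    cimp = np.array([s in cimp_subtypes for s in all_subtypes])
    logit = np.tile(base_logit[:, None], (1, len(samples)))
    # the special event probes are island CpGs but their level is governed
    # by the planted single-CpG events, not the broad CIMP offset
    island_idx = np.where(island_flag)[0]
    island_idx = island_idx[island_idx >= len(special)]
    for j, s in enumerate(all_subtypes):
        if s == "NORMAL":
            continue
        scale = 1.0 - contam_w[j]
        if cimp[j]:
            logit[island_idx, j] += cfg.cimp_offset * scale
        logit[meth_sig[s], j] += cfg.meth_signature_effect * scale
        if events.loc[samples[j], "myc_hypometh"]:
            logit[0, j] = _logit(0.30)
        if events.loc[samples[j], "mir34_hypermeth"]:
            logit[1:5, j] = base_logit[1:5] + 2.6
    noise_sd = np.full(cfg.n_cpgs, cfg.meth_noise_sd)
    noise_sd[0] = 0.4
    noise_sd[1:5] = 0.25
    beta = _expit(logit + rng.normal(0.0, 1.0, size=logit.shape) * noise_sd[:, None])
    beta = beta.clip(1e-6, 1 - 1e-6)
    if cfg.na_cell_fraction > 0:
        mask = rng.random(beta.shape) < cfg.na_cell_fraction
        beta[mask] = np.nan
    meth_annot = pd.DataFrame(
        {"cpg_island": island_flag}, index=cpg_ids
    )
    methylation = OmicsMatrix(
        pd.DataFrame(beta, index=cpg_ids, columns=samples), "methylation", meth_annot
    )

    # ----- GNL segments ----------------------------------------------------
    loss_probs, gain_probs = cfg.resolved_arm_probs()
    arms = load_arm_table()

    def expand(spec: Mapping[str, float]) -> dict[str, float]:
        out: dict[str, float] = {}
        for key, p in spec.items():
            hit = arms[(arms["arm"] == key) | (arms["chrom"] == key)]
            for a in hit["arm"]:
                out[a] = p
        return out

    seg_rows = []
    for j, sample in enumerate(samples):
        s = all_subtypes[j]
        arm_val = {a: 0 for a in arms["arm"]}
        if s != "NORMAL":
            if codel[j]:
                arm_val["1p"] = -1
                arm_val["19q"] = -1
            for spec, v in ((expand(loss_probs[s]), -1), (expand(gain_probs[s]), 1)):
                drawn_chroms: dict[str, bool] = {}
                for a, p in spec.items():
                    chrom = arms.set_index("arm").loc[a, "chrom"]
                    # one draw per chromosome-level key covers both arms
                    if a[:-1] == chrom and chrom in drawn_chroms:
                        hitp = drawn_chroms[chrom]
                    else:
                        hitp = bool(rng.random() < p)
                        drawn_chroms[chrom] = hitp
                    if hitp:
                        arm_val[a] = v
            if events.loc[sample, "max_loss"]:
                arm_val["14q"] = -1  # MAX sits on 14q; its loss is arm-level
        for _, a in arms.iterrows():
            val = arm_val[a["arm"]]
            if (
                a["arm"] == "8q"
                and s != "NORMAL"
                and events.loc[sample, "myc_gain"]
            ):
                mstart, mend = _MYC_REGION[1], _MYC_REGION[2]
                seg_rows.append((sample, a["chrom"], a["start"], mstart - 1, val))
                seg_rows.append((sample, a["chrom"], mstart, mend, 1))
                seg_rows.append((sample, a["chrom"], mend + 1, a["end"], val))
            else:
                seg_rows.append((sample, a["chrom"], a["start"], a["end"], val))
    gnl = GNLTable(
        "segment",
        segments=pd.DataFrame(
            seg_rows, columns=["sample", "chrom", "start", "end", "gnl"]
        ),
    )

    # ----- survival & annotation ------------------------------------------
    hazards = cfg.resolved_hazards()
    rt_ratio = cfg.resolved_rt_ratio()
    rt = rng.random(len(samples)) < cfg.rt_fraction
    os_time = np.full(len(samples), np.nan)
    os_event = np.full(len(samples), np.nan)
    for j, s in enumerate(all_subtypes):
        if s == "NORMAL":
            continue
        h = hazards[s] * (rt_ratio[s] if rt[j] else 1.0)
        t_event = rng.exponential(1.0 / h)
        t_cens = rng.exponential(1.0 / cfg.censor_rate) if cfg.censor_rate > 0 else np.inf
        t_cens = min(t_cens, cfg.followup_cap)
        os_time[j] = min(t_event, t_cens)
        os_event[j] = float(t_event <= t_cens)
    age = rng.normal(48.0, 10.0, size=len(samples))
    age[[s == cfg.aggressive_subtype for s in all_subtypes]] += 4.0
    grade = [
        "III" if s == cfg.aggressive_subtype else ("II" if rng.random() < 0.6 else "III")
        for s in all_subtypes
    ]
    idh = [
        "NA" if s == "NORMAL" else ("wildtype" if s in cfg.idhwt_subtypes else "mutant")
        for s in all_subtypes
    ]
    annot_df = pd.DataFrame(
        {
            "cohort": "SYNTH",
            "grade": grade,
            "histology": ["normal brain" if n else "OT" for n in is_normal],
            "idh_status": idh,
            "codel_status": codel,
            "age": np.round(age, 1),
            "os_time": os_time,
            "os_event": os_event,
            "initial_radiotherapy": rt,
            "is_normal_control": is_normal,
        },
        index=samples,
    )

    # ----- availability masks ---------------------------------------------
    avail = {}
    for omic in ("mrna", "mirna", "methylation"):
        frac = cfg.missing_fraction.get(omic, 0.0)
        keep = rng.random(len(samples)) >= frac
        keep[is_normal] = True  # controls always profiled
        avail[omic] = keep
    mrna = mrna.subset_samples([s for s, k in zip(samples, avail["mrna"]) if k])
    mirna_counts = mirna_counts.loc[
        :, [s for s, k in zip(samples, avail["mirna"]) if k]
    ]
    methylation = methylation.subset_samples(
        [s for s, k in zip(samples, avail["methylation"]) if k]
    )

    truth = pd.DataFrame(
        {
            "subtype": all_subtypes,
            "codel": codel,
            "is_normal": is_normal,
            "contamination_w": contam_w,
            "cimp": np.where(is_normal, False, cimp),
            **{e: events[e].to_numpy() for e in EVENT_NAMES},
            "any_event": np.where(is_normal, False, any_event.to_numpy()),
            "avail_mrna": avail["mrna"],
            "avail_mirna": avail["mirna"],
            "avail_methylation": avail["methylation"],
        },
        index=samples,
    )

    return SyntheticCohort(
        mrna=mrna,
        mirna_counts=mirna_counts,
        methylation=methylation,
        gnl=gnl,
        annot=annot_df,
        truth=truth,
        signature_genes=sig,
        myc_target_genes=myc_targets,
        normal_signature_genes=normal_sig,
        config=cfg,
    )


def planted_event_rates(truth: pd.DataFrame) -> pd.DataFrame:
    """Observed per-subtype frequency of each planted MYC event.

    Computed over tumour samples only; for checking the generator against
    its configured probabilities.
    """
    tum = truth[~truth["is_normal"].astype(bool)]
    return tum.groupby("subtype")[list(EVENT_NAMES)].mean()
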