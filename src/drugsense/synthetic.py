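"""Seeded synthetic cell-line panels with planted pharmacogenomic structure.

The generator emulates the statistical features of a mid-sized cancer
cell-line screen: a binary mutation matrix carrying one high-prevalence
driver mutation that controls sensitivity to a small subset of drugs,
log-normal transcript abundances, (phospho)protein readouts coupled to
transcripts through latent pathway factors (so proteins are partially
predictable from transcripts), drugs organised in classes with correlated
sensitivities, null drugs with no molecular association, a mutually
exclusive two-protein "switch", tissue-level sensitivity offsets, and
duplicate cell lines originating from the same patient.

Every panel ships with its :class:`GroundTruth` (planted coefficients,
driver flags, tissue effects, noiseless AUCs) so that downstream models
can be scored against what was actually planted.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PanelConfig",
    "GroundTruth",
    "SyntheticPanel",
    "generate_panel",
    "generate_dose_response",
    "write_panel",
    "read_panel",
]

# Number of informative continuous features planted per drug class.
N_INFORMATIVE = 5

# Named RNG substreams: adding drugs must never perturb transcript generation,
# so every matrix draws from its own child of the master seed.
_STREAMS = {
    "tissues": 0,
    "mutations": 1,
    "transcripts": 2,
    "latent": 3,
    "proteins": 4,
    "drugs": 5,
    "auc_noise": 6,
    "duplicates": 7,
    "viability": 8,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[stream],))
    )


class PanelConfigError(ValueError):
    """Raised when a PanelConfig violates its invariants."""


@dataclass
class PanelConfig:
    """Configuration of a synthetic cell-line panel.

    Defaults mirror a 49-line melanoma-style screen: 88 (phospho)protein
    antibodies, a few thousand transcripts, a driver mutation present in
    ~70% of lines, 27 variable drugs dosed on a nine-point 1:3 serial
    dilution, and a handful of duplicate lines sharing a patient.
    """

    n_cell_lines: int = 49
    n_tissues: int = 1
    n_transcripts: int = 2000
    n_proteins: int = 88
    n_mutations: int = 150
    driver_prevalence: float = 0.7
    n_drugs: int = 27
    #: (class size, shared-effect flag) per drug class; the first class is the
    #: driver-dependent one (its shared effect is the driver mutation itself).
    drug_classes: Sequence[tuple[int, bool]] = ((2, True), (3, True), (4, True))
    n_null_drugs: int = 5
    #: per-drug planted signal SD / residual AUC noise SD ratio
    effect_size: float = 1.5
    tissue_effect_sd: float = 0.1
    n_doses: int = 9
    dose_dilution_factor: float = 3.0
    viability_noise_sd: float = 0.05
    n_duplicate_patients: int = 4
    seed: int = 0
    #: SD (AUC units) of the per-line residual noise that effect_size is
    #: measured against
    auc_noise_sd: float = 0.08
    #: AUC drop caused by the driver mutation in driver-dependent drugs
    driver_effect_auc: float = 0.25
    #: if set, planted continuous effects act only in these tissues
    #: (tissue-private effects, used in cross-tissue transfer studies)
    effect_tissues: Optional[Sequence[str]] = None

    def validate(self) -> None:
        counts = {
            "n_cell_lines": self.n_cell_lines,
            "n_tissues": self.n_tissues,
            "n_transcripts": self.n_transcripts,
            "n_proteins": self.n_proteins,
            "n_mutations": self.n_mutations,
            "n_drugs": self.n_drugs,
            "n_doses": self.n_doses,
        }
        for name, value in counts.items():
            if int(value) != value or value <= 0:
                raise PanelConfigError(f"{name} must be a positive integer, got {value!r}")
        if not (0.0 < self.driver_prevalence < 1.0):
            raise PanelConfigError("driver_prevalence must be strictly between 0 and 1")
        if self.n_null_drugs < 0 or self.n_null_drugs > self.n_drugs:
            raise PanelConfigError("n_null_drugs must satisfy 0 <= n_null_drugs <= n_drugs")
        class_total = sum(size for size, _ in self.drug_classes)
        if class_total + self.n_null_drugs > self.n_drugs:
            raise PanelConfigError(
                "drug classes plus null drugs exceed n_drugs "
                f"({class_total} + {self.n_null_drugs} > {self.n_drugs})"
            )
        if self.n_proteins < 2 + N_INFORMATIVE:
            raise PanelConfigError("n_proteins too small for switch pair plus planted effects")
        if self.n_duplicate_patients < 0 or 2 * self.n_duplicate_patients > self.n_cell_lines:
            raise PanelConfigError("n_duplicate_patients too large for the panel")
        if self.dose_dilution_factor <= 1:
            raise PanelConfigError("dose_dilution_factor must exceed 1")
        for sd_name in ("tissue_effect_sd", "viability_noise_sd", "auc_noise_sd"):
            if getattr(self, sd_name) < 0:
                raise PanelConfigError(f"{sd_name} must be non-negative")


@dataclass
class GroundTruth:
    """What was planted: the answer key for parameter-recovery tests."""

    planted_coefficients: dict[str, dict[str, float]]
    driver_mutation_id: str
    driver_dependent_drugs: list[str]
    null_drugs: list[str]
    tissue_offsets: pd.DataFrame  # tissue × drug AUC shifts
    true_auc: pd.DataFrame  # cell line × drug, noiseless (pre-assay) AUC
    patient_ids: pd.Series  # cell line → patient label
    switch_pair: tuple[str, str]


@dataclass
class SyntheticPanel:
    mutation_matrix: pd.DataFrame  # binary, cell line × mutation
    transcript_matrix: pd.DataFrame  # non-negative linear scale
    protein_matrix: pd.DataFrame  # positive linear-scale intensities
    dose_response: pd.DataFrame  # long: cell_line, drug, dose, viability
    tissues: pd.Series  # cell line → tissue
    ground_truth: GroundTruth


def _cell_ids(n: int) -> list[str]:
    return [f"CL{i + 1:03d}" for i in range(n)]


def generate_panel(config: PanelConfig) -> SyntheticPanel:
    """Generate a complete synthetic panel from ``config``.

    Deterministic for a fixed seed. Proteins are noisy linear readouts of
    one matched transcript plus a latent pathway factor; drug AUCs are
    baseline + planted linear effects + tissue offset + residual noise,
    clipped to [0, 1.2]; dose–response curves are solved so their noiseless
    dose-grid mean equals the true AUC.
    """
    config.validate()
    n = config.n_cell_lines
    lines = _cell_ids(n)
    n_dup = config.n_duplicate_patients

    # --- tissues ------------------------------------------------------------
    rng_t = _rng(config.seed, "tissues")
    tissue_names = [f"tissue{i + 1}" for i in range(config.n_tissues)]
    # round-robin then shuffle: every tissue is guaranteed members
    assignment = np.array([i % config.n_tissues for i in range(n)])
    rng_t.shuffle(assignment)
    tissues = pd.Series([tissue_names[i] for i in assignment], index=lines, name="tissue")

    # --- mutations ----------------------------------------------------------
    rng_m = _rng(config.seed, "mutations")
    mut_ids = [f"MUT{i + 1:04d}" for i in range(config.n_mutations)]
    prevalences = rng_m.uniform(0.08, 0.5, size=config.n_mutations)
    prevalences[0] = config.driver_prevalence
    M = (rng_m.uniform(size=(n, config.n_mutations)) < prevalences[None, :]).astype(int)
    driver_id = mut_ids[0]

    # --- transcripts (log-normal marginals) ---------------------------------
    rng_x = _rng(config.seed, "transcripts")
    gene_mu = rng_x.normal(4.0, 2.0, size=config.n_transcripts)
    gene_sd = rng_x.uniform(0.2, 1.5, size=config.n_transcripts)
    T_log2 = gene_mu[None, :] + gene_sd[None, :] * rng_x.standard_normal((n, config.n_transcripts))

    # --- latent pathway factors --------------------------------------------
    rng_l = _rng(config.seed, "latent")
    n_factors = 3
    L = rng_l.standard_normal((n, n_factors))
    # pathway activity leaves a transcriptional signature: ~10% of genes
    # load on one factor, so transcripts partially read the same pathway
    # states the proteins do
    sig_w = 0.6
    is_sig = rng_l.random(config.n_transcripts) < 0.10
    sig_factor = rng_l.integers(0, n_factors, size=config.n_transcripts)
    sig_idx = np.nonzero(is_sig)[0]
    if sig_idx.size:
        z_orig = (T_log2[:, sig_idx] - gene_mu[sig_idx]) / gene_sd[sig_idx]
        mixed = np.sqrt(1 - sig_w**2) * z_orig + sig_w * L[:, sig_factor[sig_idx]]
        T_log2[:, sig_idx] = gene_mu[sig_idx] + gene_sd[sig_idx] * mixed

    # --- proteins: a·transcript + b·latent + noise (log2 scale) -------------
    rng_p = _rng(config.seed, "proteins")
    prot_ids = [f"PR{i + 1:03d}" for i in range(config.n_proteins)]
    a_w, b_w, noise_w = 0.5, 0.45, 0.74
    mapped = rng_p.integers(0, config.n_transcripts, size=config.n_proteins)
    factor_of = rng_p.integers(0, n_factors, size=config.n_proteins)
    prot_mu = rng_p.uniform(2.0, 6.0, size=config.n_proteins)
    Zt = (T_log2 - T_log2.mean(axis=0)) / T_log2.std(axis=0, ddof=0)
    P_log2 = (
        prot_mu[None, :]
        + a_w * Zt[:, mapped]
        + b_w * L[:, factor_of]
        + noise_w * rng_p.standard_normal((n, config.n_proteins))
    )
    # mutually exclusive switch pair: first two antibodies
    switch_state = rng_p.binomial(1, 0.5, size=n).astype(float)
    P_log2[:, 0] = 2.0 + 2.0 * switch_state + 0.35 * rng_p.standard_normal(n)
    P_log2[:, 1] = 4.0 - 2.0 * switch_state + 0.35 * rng_p.standard_normal(n)
    switch_pair = (prot_ids[0], prot_ids[1])

    # --- duplicate cell lines (before planting effects) ---------------------
    rng_d = _rng(config.seed, "duplicates")
    patient_ids = pd.Series([f"PAT{i + 1:03d}" for i in range(n)], index=lines, name="patient")
    for k in range(n_dup):
        src, dst = k, n - n_dup + k
        M[dst] = M[src]
        T_log2[dst] = T_log2[src] + 0.05 * gene_sd * rng_d.standard_normal(config.n_transcripts)
        p_sd = P_log2.std(axis=0, ddof=0)
        P_log2[dst] = P_log2[src] + 0.05 * p_sd * rng_d.standard_normal(config.n_proteins)
        tissues.iloc[dst] = tissues.iloc[src]
        patient_ids.iloc[dst] = patient_ids.iloc[src]

    # --- drugs and planted effects -----------------------------------------
    rng_g = _rng(config.seed, "drugs")
    drug_ids = [f"DRUG{i + 1:02d}" for i in range(config.n_drugs)]
    classes = list(config.drug_classes)
    cursor = 0
    class_members: list[list[str]] = []
    for size, _shared in classes:
        class_members.append(drug_ids[cursor : cursor + size])
        cursor += size
    null_drugs = drug_ids[config.n_drugs - config.n_null_drugs :] if config.n_null_drugs else []
    singleton_drugs = drug_ids[cursor : config.n_drugs - config.n_null_drugs]
    driver_drugs = list(class_members[0]) if class_members else []

    baseline = rng_g.uniform(0.3, 0.8, size=config.n_drugs)
    signal_sd = config.effect_size * config.auc_noise_sd

    Zp = (P_log2 - P_log2.mean(axis=0)) / P_log2.std(axis=0, ddof=0)
    effect_mask = np.ones(n, dtype=bool)
    if config.effect_tissues is not None:
        effect_mask = tissues.isin(list(config.effect_tissues)).to_numpy()

    # features available for planting: proteins excluding the switch pair
    available = list(range(2, config.n_proteins))
    rng_g.shuffle(available)

    planted: dict[str, dict[str, float]] = {d: {} for d in drug_ids}
    signal = np.zeros((n, config.n_drugs))

    def _draw_coef() -> np.ndarray:
        # pathway-coherent markers: every planted feature is genuinely
        # informative (magnitude bounded away from zero) and the signs are
        # coherent, mirroring antibody sets that read out one pathway
        mags = rng_g.uniform(0.5, 1.5, size=N_INFORMATIVE)
        return mags * rng_g.choice([-1.0, 1.0])

    def _pick_features() -> list[int]:
        # prefer proteins sharing one latent pathway factor so the drug's
        # signal aligns with a coherent direction of the proteome
        nonlocal available
        f = int(rng_g.integers(0, n_factors))
        same = [j for j in available if factor_of[j] == f]
        feats = same[:N_INFORMATIVE]
        if len(feats) < N_INFORMATIVE:
            others = [j for j in available if j not in feats]
            feats = feats + others[: N_INFORMATIVE - len(feats)]
        available = [j for j in available if j not in feats] + feats  # recycle
        return feats

    def _plant_block(drugs: list[str], shared: bool) -> None:
        feats = _pick_features()
        shared_coef = _draw_coef()
        for d in drugs:
            if shared:
                own = _draw_coef()
                coef = np.sqrt(0.8) * shared_coef + np.sqrt(0.2) * own
            else:
                coef = _draw_coef()
            raw = Zp[:, feats] @ coef
            sd = raw.std(ddof=0)
            scale = signal_sd / sd if sd > 0 else 0.0
            coef = coef * scale
            j = drug_ids.index(d)
            signal[:, j] = np.where(effect_mask, Zp[:, feats] @ coef, 0.0)
            for f_idx, c in zip(feats, coef):
                planted[d][prot_ids[f_idx]] = float(c)

    for members, (size, shared) in zip(class_members[1:], classes[1:]):
        _plant_block(members, shared)
    for d in singleton_drugs:
        _plant_block([d], False)

    # driver class: sensitivity controlled by the driver mutation
    for d in driver_drugs:
        j = drug_ids.index(d)
        signal[:, j] = -config.driver_effect_auc * M[:, 0]
        planted[d][driver_id] = -config.driver_effect_auc

    # tissue offsets
    tissue_offsets = pd.DataFrame(
        rng_g.normal(0.0, config.tissue_effect_sd, size=(config.n_tissues, config.n_drugs))
        if config.n_tissues > 1
        else np.zeros((config.n_tissues, config.n_drugs)),
        index=tissue_names,
        columns=drug_ids,
    )
    offsets = tissue_offsets.loc[tissues.values].to_numpy()

    rng_e = _rng(config.seed, "auc_noise")
    resid = rng_e.normal(0.0, config.auc_noise_sd, size=(n, config.n_drugs))
    # duplicate lines share their source's residual up to a small perturbation
    for k in range(n_dup):
        src, dst = k, n - n_dup + k
        resid[dst] = resid[src] + 0.25 * config.auc_noise_sd * rng_e.standard_normal(
            config.n_drugs
        )

    true_auc = np.clip(baseline[None, :] + signal + offsets + resid, 0.0, 1.2)
    true_auc_df = pd.DataFrame(true_auc, index=lines, columns=drug_ids)

    ground_truth = GroundTruth(
        planted_coefficients=planted,
        driver_mutation_id=driver_id,
        driver_dependent_drugs=driver_drugs,
        null_drugs=list(null_drugs),
        tissue_offsets=tissue_offsets,
        true_auc=true_auc_df,
        patient_ids=patient_ids,
        switch_pair=switch_pair,
    )

    dose_response = generate_dose_response(true_auc_df, config)

    transcript_matrix = pd.DataFrame(
        np.clip(np.exp2(T_log2) - 1.0, 0.0, None),
        index=lines,
        columns=[f"TR{i + 1:05d}" for i in range(config.n_transcripts)],
    )
    protein_matrix = pd.DataFrame(np.exp2(P_log2), index=lines, columns=prot_ids)
    mutation_matrix = pd.DataFrame(M, index=lines, columns=mut_ids)

    return SyntheticPanel(
        mutation_matrix=mutation_matrix,
        transcript_matrix=transcript_matrix,
        protein_matrix=protein_matrix,
        dose_response=dose_response,
        tissues=tissues,
        ground_truth=ground_truth,
    )


# ---------------------------------------------------------------------------
# dose–response curves
# ---------------------------------------------------------------------------

_HILL_SLOPE = 1.25  # fixed steepness of the logistic response in log-dose


def _solve_viability_curves(auc: np.ndarray, n_doses: int) -> np.ndarray:
    """Noiseless viability curves (rows) whose dose-grid mean equals ``auc``.

    Four-parameter logistic in log-dose with upper asymptote 1; the lower
    asymptote is max(0, 2·AUC − 1) and the inflection point is solved by
    bisection so that the arithmetic mean over the evenly log-spaced grid
    matches the target exactly. AUC ≥ 1 (growth stimulation) and AUC ≤ 0
    degenerate to flat curves.
    """
    auc = np.asarray(auc, dtype=float)
    m = auc.size
    x = np.arange(n_doses, dtype=float)  # grid index == log_f(dose/min_dose)
    curves = np.empty((m, n_doses))

    flat = (auc >= 1.0) | (auc <= 0.0)
    curves[flat] = np.clip(auc[flat], 0.0, None)[:, None]

    idx = ~flat
    if np.any(idx):
        target = auc[idx]
        lower = np.maximum(0.0, 2.0 * target - 1.0)
        lo = np.full(target.shape, -60.0)
        hi = np.full(target.shape, n_doses + 60.0)
        for _ in range(100):
            mid = 0.5 * (lo + hi)
            v = lower[:, None] + (1.0 - lower[:, None]) / (
                1.0 + np.exp(_HILL_SLOPE * (x[None, :] - mid[:, None]))
            )
            mean = v.mean(axis=1)
            too_low = mean < target
            lo = np.where(too_low, mid, lo)
            hi = np.where(too_low, hi, mid)
        mid = 0.5 * (lo + hi)
        curves[idx] = lower[:, None] + (1.0 - lower[:, None]) / (
            1.0 + np.exp(_HILL_SLOPE * (x[None, :] - mid[:, None]))
        )
    return curves


def generate_dose_response(true_auc: pd.DataFrame, config: PanelConfig) -> pd.DataFrame:
    """Long-format viability table realising ``true_auc`` on the dose grid.

    Doses follow an evenly log-spaced 1:``dose_dilution_factor`` serial
    dilution (``n_doses`` points, highest dose 10 concentration units).
    Additive Gaussian noise with SD ``viability_noise_sd`` is applied and
    viabilities clipped at zero.
    """
    arr = true_auc.to_numpy(dtype=float)
    if np.any(arr < 0.0) or np.any(arr > 1.2):
        raise ValueError("true AUC values must lie in [0, 1.2]")
    lines = list(true_auc.index)
    drugs = list(true_auc.columns)
    n_doses = config.n_doses
    max_dose = 10.0
    doses = max_dose / config.dose_dilution_factor ** np.arange(n_doses - 1, -1, -1)

    curves = _solve_viability_curves(arr.ravel(), n_doses)
    rng_v = _rng(config.seed, "viability")
    if config.viability_noise_sd > 0:
        curves = curves + rng_v.normal(0.0, config.viability_noise_sd, size=curves.shape)
    curves = np.clip(curves, 0.0, None)

    n_pairs = len(lines) * len(drugs)
    rec = pd.DataFrame(
        {
            "cell_line": np.repeat([ln for ln in lines for _ in drugs], n_doses),
            "drug": np.repeat(drugs * len(lines), n_doses),
            "dose": np.tile(doses, n_pairs),
            "viability": curves.ravel(),
        }
    )
    return rec


# ---------------------------------------------------------------------------
# panel I/O (plain-text formats)
# ---------------------------------------------------------------------------


def write_panel(panel: SyntheticPanel, out_dir: str) -> None:
    """Write a panel as TSV/CSV/JSON files under ``out_dir``."""
    os.makedirs(out_dir, exist_ok=True)
    panel.mutation_matrix.to_csv(os.path.join(out_dir, "mutations.tsv"), sep="\t")
    panel.transcript_matrix.to_csv(
        os.path.join(out_dir, "transcripts.tsv"), sep="\t", float_format="%.6g"
    )
    panel.protein_matrix.to_csv(
        os.path.join(out_dir, "proteins.tsv"), sep="\t", float_format="%.6g"
    )
    panel.dose_response.to_csv(os.path.join(out_dir, "dose_response.csv"), index=False)
    ann = pd.DataFrame(
        {"tissue": panel.tissues, "patient": panel.ground_truth.patient_ids}
    )
    ann.to_csv(os.path.join(out_dir, "annotations.tsv"), sep="\t", index_label="cell_line")
    gt = panel.ground_truth
    payload = {
        "planted_coefficients": gt.planted_coefficients,
        "driver_mutation_id": gt.driver_mutation_id,
        "driver_dependent_drugs": gt.driver_dependent_drugs,
        "null_drugs": gt.null_drugs,
        "tissue_offsets": gt.tissue_offsets.to_dict(orient="index"),
        "true_auc": gt.true_auc.to_dict(orient="index"),
        "patient_ids": gt.patient_ids.to_dict(),
        "switch_pair": list(gt.switch_pair),
    }
    with open(os.path.join(out_dir, "ground_truth.json"), "w") as fh:
        json.dump(payload, fh, indent=1)


def read_panel(panel_dir: str) -> SyntheticPanel:
    """Read a panel previously written with :func:`write_panel`."""
    mut = pd.read_csv(os.path.join(panel_dir, "mutations.tsv"), sep="\t", index_col=0)
    tr = pd.read_csv(os.path.join(panel_dir, "transcripts.tsv"), sep="\t", index_col=0)
    pr = pd.read_csv(os.path.join(panel_dir, "proteins.tsv"), sep="\t", index_col=0)
    dr = pd.read_csv(os.path.join(panel_dir, "dose_response.csv"))
    ann = pd.read_csv(os.path.join(panel_dir, "annotations.tsv"), sep="\t", index_col=0)
    with open(os.path.join(panel_dir, "ground_truth.json")) as fh:
        payload = json.load(fh)
    gt = GroundTruth(
        planted_coefficients=payload["planted_coefficients"],
        driver_mutation_id=payload["driver_mutation_id"],
        driver_dependent_drugs=payload["driver_dependent_drugs"],
        null_drugs=payload["null_drugs"],
        tissue_offsets=pd.DataFrame.from_dict(payload["tissue_offsets"], orient="index"),
        true_auc=pd.DataFrame.from_dict(payload["true_auc"], orient="index"),
        patient_ids=pd.Series(payload["patient_ids"], name="patient"),
        switch_pair=tuple(payload["switch_pair"]),
    )
    return SyntheticPanel(
        mutation_matrix=mut,
        transcript_matrix=tr,
        protein_matrix=pr,
        dose_response=dr,
        tissues=ann["tissue"],
        ground_truth=gt,
    )
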