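"""Synthetic two-strain isobaric-tag datasets with known ground truth.

Emulates the post-search PSM tables of two experiments on a high-toxin (HT)
and a low-toxin (LT) dinoflagellate strain:

* a 4-channel differential-cysteine-labeling (iodoTMT) design measuring
  per-protein redox stoichiometry — reduced cysteines carry the light label,
  oxidized cysteines (reduced afterwards with TCEP) the heavy label, so the
  light/(light+heavy) intensity ratio is the in-vivo reduced fraction;
* an 11-channel amine-reactive TMT design measuring protein abundance,
  with 5 replicates per strain plus one pooled reference channel, optionally
  including a degenerate low-yield channel.

Ground truth (abundances, fold changes, reduced fractions, annotations)
is retained so every downstream stage can be tested by recovery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .tables import (
    ChannelDesign,
    ROLE_ABUNDANCE,
    ROLE_OXIDIZED,
    ROLE_REDUCED,
    ROLE_REFERENCE,
    STRAIN_HT,
    STRAIN_LT,
    STRAIN_REF,
    write_table,
)

log = logging.getLogger(__name__)


class ParameterError(ValueError):
    """A simulation parameter is out of range or internally inconsistent."""


# default TMT-11 reporter channel names: 5 HT, 5 LT, pooled reference
TMT11_HT_CHANNELS = ("126", "127N", "127C", "128N", "129N")
TMT11_LT_CHANNELS = ("128C", "129C", "130C", "130N", "131N")
TMT11_REF_CHANNEL = "131C"

COMPARTMENTS = ("cytoplasm", "plastid", "mitochondrion", "nucleus", "secreted")


@dataclass(frozen=True)
class TermSpec:
    """One annotation term: its size and how strongly it tracks true DAPs.

    ``dap_bias`` is the fraction of members drawn preferentially from
    proteins with a true positive fold change (HT-up); the remainder are
    drawn uniformly.  ``parent`` makes the term a subset of another term's
    members (e.g. the polyketide-synthase subset of COG Q).
    """

    name: str
    n_members: int
    dap_bias: float = 0.0
    parent: str | None = None


@dataclass(frozen=True)
class DegenerateChannel:
    """A low-yield plex channel: attenuated intensity, extra missingness."""

    channel_id: str = "129N"
    attenuation: float = 0.01
    extra_missing_rate: float = 0.5


def default_annotation_scheme() -> tuple[TermSpec, ...]:
    """COG-style scheme: Q (secondary metabolites) with a PKS subset that
    tracks the abundance signal, two mildly associated terms, and neutral
    housekeeping categories."""
    return (
        TermSpec("Q", 120, dap_bias=0.5),
        TermSpec("Q_PKS", 48, dap_bias=0.8, parent="Q"),
        TermSpec("A", 80, dap_bias=0.2),
        TermSpec("T", 100, dap_bias=0.2),
        TermSpec("C", 150),
        TermSpec("O", 130),
        TermSpec("J", 110),
    )


@dataclass
class SimConfig:
    """Generator parameters; defaults reproduce the study's conditions.

    Reduced-fraction Beta moments default to the strain averages of the
    redox experiment (HT 0.28 ± 0.15, LT 0.37 ± 0.19); the paired-mode
    ratio median defaults to the reported median stoichiometry fold change
    (0.78); true log2 fold changes of differentially abundant proteins are
    uniform on ``log2fc_range`` with ``dap_up_fraction`` positive.
    """

    n_proteins: int = 2000
    n_replicates_redox: int = 4
    n_replicates_abundance: int = 5
    # PSM (and cysteine-peptide) counts per protein: 1 + NegBinom(mean-1, dispersion)
    psm_mean: float = 6.0
    psm_dispersion: float = 2.0
    peptide_factor_sigma: float = 0.8  # log-normal spread of per-peptide response
    base_abundance_median: float = 1e5
    base_abundance_sigma: float = 1.2  # natural-log sd
    noise_cv: float = 0.1
    missing_rate: float = 0.05
    dap_fraction: float = 0.2
    dap_up_fraction: float = 0.45
    log2fc_range: tuple[float, float] = (1.0, 4.0)
    redox_mean_ht: float = 0.28
    redox_sd_ht: float = 0.15
    redox_mean_lt: float = 0.37
    redox_sd_lt: float = 0.19
    paired_redox: bool = False
    fc_pairing_median: float = 0.78
    fc_pairing_sigma: float = 0.1
    degenerate_channel: DegenerateChannel | None = field(default_factory=DegenerateChannel)
    annotation_scheme: tuple[TermSpec, ...] = field(default_factory=default_annotation_scheme)
    merge_group_size: int = 18
    merge_group_label: str = "LHCII"
    seed: int = 0

    def validate(self) -> None:
        for name in ("missing_rate", "dap_fraction", "dap_up_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name}={v} outside [0, 1]")
        if self.noise_cv < 0:
            raise ParameterError("noise_cv must be >= 0")
        if self.n_proteins < 1:
            raise ParameterError("n_proteins must be >= 1")
        lo, hi = self.log2fc_range
        if lo < 0 or hi < lo:
            raise ParameterError(f"bad log2fc_range {self.log2fc_range}")
        _beta_params(self.redox_mean_lt, self.redox_sd_lt)
        if not self.paired_redox:
            _beta_params(self.redox_mean_ht, self.redox_sd_ht)
        elif self.fc_pairing_median <= 0:
            raise ParameterError("fc_pairing_median must be positive")
        if self.degenerate_channel is not None:
            d = self.degenerate_channel
            if not 0 < d.attenuation <= 1 or not 0 <= d.extra_missing_rate <= 1:
                raise ParameterError("bad degenerate channel parameters")

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["annotation_scheme"] = [asdict(t) for t in self.annotation_scheme]
        data["log2fc_range"] = list(self.log2fc_range)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        data = yaml.safe_load(Path(path).read_text())
        if data.get("annotation_scheme") is not None:
            data["annotation_scheme"] = tuple(TermSpec(**t) for t in data["annotation_scheme"])
        if data.get("degenerate_channel") is not None:
            data["degenerate_channel"] = DegenerateChannel(**data["degenerate_channel"])
        if data.get("log2fc_range") is not None:
            data["log2fc_range"] = tuple(data["log2fc_range"])
        return cls(**data)


@dataclass
class SimTruth:
    """Ground truth per protein plus the annotation catalog.

    ``proteins`` columns: protein_id, base_abundance, log2_fc, is_dap,
    reduced_fraction_ht, reduced_fraction_lt, n_cys_peptides, compartment,
    merge_group (empty string when the protein is not part of a merge group).
    """

    proteins: pd.DataFrame
    annotations: dict[str, frozenset[str]]

    @property
    def catalog_with_compartments(self) -> dict[str, frozenset[str]]:
        """Annotation terms plus a ``loc:<compartment>`` label per protein."""
        out = {}
        for pid, comp in zip(self.proteins["protein_id"], self.proteins["compartment"]):
            out[pid] = frozenset(self.annotations.get(pid, frozenset()) | {f"loc:{comp}"})
        return out

    def merge_group_map(self) -> dict[str, str]:
        sub = self.proteins[self.proteins["merge_group"] != ""]
        return dict(zip(sub["protein_id"], sub["merge_group"]))

    def write(self, path: str | Path, force: bool = False) -> Path:
        return write_table(self.proteins, path, force=force)


def _beta_params(mean: float, sd: float) -> tuple[float, float]:
    """Shape parameters of a Beta law with the given mean and sd."""
    if not 0 < mean < 1:
        raise ParameterError(f"Beta mean {mean} outside (0, 1)")
    var = sd * sd
    if var <= 0 or var >= mean * (1 - mean):
        raise ParameterError(
            f"infeasible Beta moments: need 0 < sd^2 < mean*(1-mean); "
            f"got mean={mean}, sd={sd}"
        )
    nu = mean * (1 - mean) / var - 1.0
    return mean * nu, (1 - mean) * nu


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative log-normal noise with unit mean and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    sigma = np.sqrt(sigma2)
    return rng.lognormal(-sigma2 / 2.0, sigma, size)


def _nb_counts(rng: np.random.Generator, mean: float, dispersion: float, n: int) -> np.ndarray:
    """1 + negative-binomial counts (so every protein has >= 1 peptide/PSM)."""
    mu = max(mean - 1.0, 1e-9)
    r = dispersion
    p = r / (r + mu)
    return 1 + rng.negative_binomial(r, p, n)


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

def simulate_ground_truth(config: SimConfig) -> SimTruth:
    """Draw per-protein truth: abundance, fold change, reduced fractions,
    peptide counts, annotations, compartments and merge groups.

    Exactly ``round(dap_fraction * n)`` proteins get a nonzero true log2
    fold change with magnitude uniform on ``log2fc_range``; the rest are
    exactly 0.  Reduced fractions come from the two strain Beta laws, or in
    paired mode from LT ~ Beta and HT = r·LT with log r normal (median
    ``fc_pairing_median``, sd ``fc_pairing_sigma``), truncated to (0, 1].
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    n = config.n_proteins
    ids = np.array([f"P{i:05d}" for i in range(n)])

    base = config.base_abundance_median * rng.lognormal(
        0.0, config.base_abundance_sigma, n
    )

    n_dap = int(round(config.dap_fraction * n))
    log2_fc = np.zeros(n)
    dap_idx = rng.choice(n, size=n_dap, replace=False)
    lo, hi = config.log2fc_range
    mags = rng.uniform(lo, hi, n_dap)
    n_up = int(round(config.dap_up_fraction * n_dap))
    signs = np.concatenate([np.ones(n_up), -np.ones(n_dap - n_up)])
    rng.shuffle(signs)
    log2_fc[dap_idx] = mags * signs

    a_lt, b_lt = _beta_params(config.redox_mean_lt, config.redox_sd_lt)
    rf_lt = rng.beta(a_lt, b_lt, n)
    if config.paired_redox:
        ratio = np.exp(rng.normal(np.log(config.fc_pairing_median),
                                  config.fc_pairing_sigma, n))
        rf_ht = np.minimum(ratio * rf_lt, 1.0)
    else:
        a_ht, b_ht = _beta_params(config.redox_mean_ht, config.redox_sd_ht)
        rf_ht = rng.beta(a_ht, b_ht, n)

    n_cys = _nb_counts(rng, config.psm_mean, config.psm_dispersion, n)
    compartments = rng.choice(COMPARTMENTS, size=n,
                              p=[0.45, 0.2, 0.15, 0.12, 0.08])

    merge_group = np.full(n, "", dtype=object)
    if config.merge_group_size > 0:
        non_dap = np.setdiff1d(np.arange(n), dap_idx)
        pool = non_dap if len(non_dap) >= config.merge_group_size else np.arange(n)
        members = rng.choice(pool, size=min(config.merge_group_size, len(pool)),
                             replace=False)
        merge_group[members] = config.merge_group_label

    annotations = _assign_annotations(rng, ids, log2_fc, config.annotation_scheme)

    proteins = pd.DataFrame(
        {
            "protein_id": ids,
            "base_abundance": base,
            "log2_fc": log2_fc,
            "is_dap": log2_fc != 0.0,
            "reduced_fraction_ht": rf_ht,
            "reduced_fraction_lt": rf_lt,
            "n_cys_peptides": n_cys,
            "compartment": compartments,
            "merge_group": merge_group,
        }
    )
    return SimTruth(proteins=proteins, annotations=annotations)


def _assign_annotations(
    rng: np.random.Generator,
    ids: np.ndarray,
    log2_fc: np.ndarray,
    scheme: Sequence[TermSpec],
) -> dict[str, frozenset[str]]:
    """Assign term memberships; top-level terms are disjoint, child terms
    are subsets of their parent's members."""
    n = len(ids)
    up_idx = set(np.flatnonzero(log2_fc > 0).tolist())
    available = set(range(n))
    members_of: dict[str, np.ndarray] = {}
    annotations: dict[str, set[str]] = {}

    for term in scheme:
        if term.parent is None:
            size = min(term.n_members, len(available))
            n_biased = int(round(term.dap_bias * size))
            up_avail = sorted(available & up_idx)
            take_up = rng.choice(up_avail, size=min(n_biased, len(up_avail)),
                                 replace=False) if up_avail and n_biased else np.array([], int)
            rest_pool = sorted(available - set(take_up.tolist()))
            take_rest = rng.choice(rest_pool, size=size - len(take_up), replace=False)
            chosen = np.concatenate([take_up, take_rest]).astype(int)
            available -= set(chosen.tolist())
        else:
            parent = members_of.get(term.parent)
            if parent is None:
                raise ParameterError(f"term {term.name} declared before parent {term.parent}")
            size = min(term.n_members, len(parent))
            n_biased = int(round(term.dap_bias * size))
            p_up = np.array([i in up_idx for i in parent])
            up_pool = parent[p_up]
            take_up = rng.choice(up_pool, size=min(n_biased, len(up_pool)),
                                 replace=False) if len(up_pool) and n_biased else np.array([], int)
            rest_pool = np.setdiff1d(parent, take_up)
            take_rest = rng.choice(rest_pool, size=size - len(take_up), replace=False)
            chosen = np.concatenate([take_up, take_rest]).astype(int)
        members_of[term.name] = np.sort(chosen)
        for i in chosen:
            annotations.setdefault(ids[i], set()).add(term.name)

    return {k: frozenset(v) for k, v in annotations.items()}


# ---------------------------------------------------------------------------
# iodoTMT (redox) PSM simulation
# ---------------------------------------------------------------------------

def iodotmt_design(n_replicates: int) -> ChannelDesign:
    """One 4-channel plex per replicate: light 126/127 label the reduced
    cysteines of HT/LT, heavy 130/131 the TCEP-reduced (originally oxidized)
    cysteines."""
    rows = []
    for k in range(1, n_replicates + 1):
        rows += [
            (f"run{k}_126", STRAIN_HT, k, ROLE_REDUCED),
            (f"run{k}_127", STRAIN_LT, k, ROLE_REDUCED),
            (f"run{k}_130", STRAIN_HT, k, ROLE_OXIDIZED),
            (f"run{k}_131", STRAIN_LT, k, ROLE_OXIDIZED),
        ]
    frame = pd.DataFrame(rows, columns=["channel_id", "strain", "replicate", "role"])
    frame["replicate"] = frame["replicate"].astype("Int64")
    return ChannelDesign(frame)


def simulate_iodotmt_psms(truth: SimTruth, config: SimConfig) -> tuple[pd.DataFrame, ChannelDesign]:
    """PSM-level reporter intensities for the differential-labeling design.

    For protein p with abundance A, reduced fraction f and peptide response
    factor g: expected light intensity is A·f·g and expected heavy intensity
    A·(1−f)·g, each multiplied by i.i.d. log-normal noise with CV
    ``noise_cv`` and masked missing with probability ``missing_rate``.
    Equal protein amounts of both strains enter each run, so abundance fold
    changes play no role here.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    design = iodotmt_design(config.n_replicates_redox)

    prot = truth.proteins
    pep_counts = prot["n_cys_peptides"].to_numpy()
    prot_idx = np.repeat(np.arange(len(prot)), pep_counts)
    total_peps = int(pep_counts.sum())
    pep_rank = np.concatenate([np.arange(c) for c in pep_counts])
    pep_ids = np.array(
        [f"{pid}_cys{j}" for pid, j in
         zip(prot["protein_id"].to_numpy()[prot_idx], pep_rank)]
    )
    # per-peptide response factor, shared across runs and channels
    pep_factor = rng.lognormal(0.0, config.peptide_factor_sigma, total_peps)
    base = prot["base_abundance"].to_numpy()[prot_idx] * pep_factor
    rf = {
        STRAIN_HT: prot["reduced_fraction_ht"].to_numpy()[prot_idx],
        STRAIN_LT: prot["reduced_fraction_lt"].to_numpy()[prot_idx],
    }

    frames = []
    for k in range(1, config.n_replicates_redox + 1):
        cols: dict[str, np.ndarray] = {}
        for strain, tag in ((STRAIN_HT, "126"), (STRAIN_LT, "127")):
            cols[f"run{k}_{tag}"] = base * rf[strain]
        for strain, tag in ((STRAIN_HT, "130"), (STRAIN_LT, "131")):
            cols[f"run{k}_{tag}"] = base * (1.0 - rf[strain])
        block = pd.DataFrame(
            {
                "protein_id": prot["protein_id"].to_numpy()[prot_idx],
                "peptide_id": pep_ids,
                "run_id": f"run{k}",
            }
        )
        for name, expected in cols.items():
            vals = expected * _lognormal_noise(rng, config.noise_cv, total_peps)
            if config.missing_rate > 0:
                vals = np.where(rng.random(total_peps) < config.missing_rate,
                                np.nan, vals)
            block[name] = vals
        frames.append(block)

    psms = pd.concat(frames, ignore_index=True)
    # rows only carry their own run's channels; others are structurally missing
    full = psms.reindex(columns=["protein_id", "peptide_id", "run_id"] + design.channels)
    return full, design


# ---------------------------------------------------------------------------
# TMT-11plex (abundance) PSM simulation
# ---------------------------------------------------------------------------

def tmt11_design(n_replicates: int = 5) -> ChannelDesign:
    """5 HT + 5 LT sample channels plus the pooled reference channel."""
    rows = []
    if n_replicates == 5:
        ht, lt = TMT11_HT_CHANNELS, TMT11_LT_CHANNELS
    else:
        ht = tuple(f"HT_{k}" for k in range(1, n_replicates + 1))
        lt = tuple(f"LT_{k}" for k in range(1, n_replicates + 1))
    for k, ch in enumerate(ht, start=1):
        rows.append((ch, STRAIN_HT, k, ROLE_ABUNDANCE))
    for k, ch in enumerate(lt, start=1):
        rows.append((ch, STRAIN_LT, k, ROLE_ABUNDANCE))
    rows.append((TMT11_REF_CHANNEL if n_replicates == 5 else "REF",
                 STRAIN_REF, pd.NA, ROLE_REFERENCE))
    frame = pd.DataFrame(rows, columns=["channel_id", "strain", "replicate", "role"])
    frame["replicate"] = frame["replicate"].astype("Int64")
    return ChannelDesign(frame)


def simulate_tmt_psms(truth: SimTruth, config: SimConfig) -> tuple[pd.DataFrame, ChannelDesign]:
    """PSM-level reporter intensities for the 11-plex abundance design.

    The true log2 fold change is split symmetrically: HT channels expect
    A·g·2^(fc/2), LT channels A·g·2^(−fc/2), so the HT−LT difference of
    log2 expectations equals the true fold change.  The reference channel's
    expectation is the arithmetic mean of the ten sample expectations.  An
    optional degenerate channel is attenuated and given extra missingness.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 2])
    design = tmt11_design(config.n_replicates_abundance)
    if config.degenerate_channel is not None:
        if config.degenerate_channel.channel_id not in design.channels:
            raise ParameterError(
                f"degenerate channel {config.degenerate_channel.channel_id!r} "
                "not in the design"
            )

    prot = truth.proteins
    psm_counts = _nb_counts(rng, config.psm_mean, config.psm_dispersion, len(prot))
    prot_idx = np.repeat(np.arange(len(prot)), psm_counts)
    total = int(psm_counts.sum())
    psm_rank = np.concatenate([np.arange(c) for c in psm_counts])
    pep_ids = np.array(
        [f"{pid}_psm{j}" for pid, j in
         zip(prot["protein_id"].to_numpy()[prot_idx], psm_rank)]
    )
    pep_factor = rng.lognormal(0.0, config.peptide_factor_sigma, total)
    base = prot["base_abundance"].to_numpy()[prot_idx] * pep_factor
    fc = prot["log2_fc"].to_numpy()[prot_idx]
    exp_ht = base * np.exp2(fc / 2.0)
    exp_lt = base * np.exp2(-fc / 2.0)
    exp_ref = (exp_ht + exp_lt) / 2.0  # mean of 5 identical HT + 5 identical LT

    psms = pd.DataFrame(
        {
            "protein_id": prot["protein_id"].to_numpy()[prot_idx],
            "peptide_id": pep_ids,
            "run_id": "plex1",
        }
    )
    strain_of = dict(zip(design.frame["channel_id"], design.frame["strain"]))
    for ch in design.channels:
        expected = {STRAIN_HT: exp_ht, STRAIN_LT: exp_lt, STRAIN_REF: exp_ref}[strain_of[ch]]
        vals = expected * _lognormal_noise(rng, config.noise_cv, total)
        miss = config.missing_rate
        if config.degenerate_channel is not None and ch == config.degenerate_channel.channel_id:
            vals = vals * config.degenerate_channel.attenuation
            miss = 1.0 - (1.0 - miss) * (1.0 - config.degenerate_channel.extra_missing_rate)
        if miss > 0:
            vals = np.where(rng.random(total) < miss, np.nan, vals)
        psms[ch] = vals
    return psms, design
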