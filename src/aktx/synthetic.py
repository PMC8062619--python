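"""Synthetic study generator: panel, counts, cohort, lesions, networks.

The trial this package models profiled actinic keratosis (AK) biopsies on a
modified PanCancer immune panel (770 base genes plus 18 spiked immune genes,
788 measured genes in total) before and after topical imiquimod, in a cohort
of 19 analyzable patients of whom 14 had matched pre/post biopsies. No counts
are publicly deposited, so every downstream stage here is exercised on
synthetic data that reproduces the *structure* of that study:

* a panel manifest with endogenous, housekeeping and spiked probes plus the
  positive-control ladder A..F (decreasing concentration; POS_F sets the
  lower limit of detection) and negative controls;
* negative-binomial (gamma-Poisson) counts with per-sample library-size
  factors, low-variance housekeeping genes, and planted log2 fold-change
  effects between post vs pre samples and between complete responders (CR)
  and incomplete responders (IR);
* per-patient lesion counts (Lmax during treatment vs week-14 count) with
  CR defined as zero lesions at week 14;
* background signaling networks with mixed directed/undirected edges and
  optional planted key-driver hubs.

Every generator is a pure function of its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .network import BackgroundNetwork

PROBE_CLASSES = ("endogenous", "housekeeping", "spike_in", "positive_control", "negative_control")
MEASURED_CLASSES = ("endogenous", "housekeeping", "spike_in")
POS_LABELS = "ABCDEF"

# POS_F ends up around 8 counts: the scale at which the lowest spike of a
# 1:4 ladder is typically observed, and low enough that the dimmest genes
# fall under the detection limit.
POS_LADDER_TOP = 128.0
POS_LADDER_RATIO = 0.25
POS_COUNT_SCALE = 64.0
NEG_BACKGROUND_MEAN = 2.0


class ConfigurationError(ValueError):
    """Raised when a generator configuration is infeasible."""


# ---------------------------------------------------------------------------
# panel manifest
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Probe:
    gene_id: str
    probe_class: str
    control_label: str | None = None
    nominal_concentration: float | None = None


@dataclass(frozen=True)
class PanelManifest:
    """Probe annotation for one panel: what each count row is."""

    probes: tuple[Probe, ...]

    def __post_init__(self) -> None:
        ids = [p.gene_id for p in self.probes]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate gene_ids in manifest")
        pos = [p for p in self.probes if p.probe_class == "positive_control"]
        labels = [p.control_label for p in pos]
        if len(set(labels)) != len(labels) or any(l not in POS_LABELS for l in labels):
            raise ConfigurationError("positive-control labels must be distinct members of A..F")
        conc = [p.nominal_concentration for p in sorted(pos, key=lambda p: p.control_label)]
        if any(c is None or c <= 0 for c in conc):
            raise ConfigurationError("positive controls need positive nominal concentrations")
        if any(a <= b for a, b in zip(conc, conc[1:])):
            raise ConfigurationError("positive-control concentrations must strictly decrease A..F")
        for p in self.probes:
            if p.probe_class not in PROBE_CLASSES:
                raise ConfigurationError(f"unknown probe class {p.probe_class!r}")

    def genes_of_class(self, probe_class: str) -> tuple[str, ...]:
        return tuple(p.gene_id for p in self.probes if p.probe_class == probe_class)

    @property
    def measured_genes(self) -> tuple[str, ...]:
        """Genes reported as expression values (controls excluded)."""
        return tuple(p.gene_id for p in self.probes if p.probe_class in MEASURED_CLASSES)

    @property
    def housekeeping_genes(self) -> tuple[str, ...]:
        return self.genes_of_class("housekeeping")

    @property
    def control_genes(self) -> tuple[str, ...]:
        return tuple(
            p.gene_id
            for p in self.probes
            if p.probe_class in ("positive_control", "negative_control")
        )

    def positive_control(self, label: str) -> Probe:
        for p in self.probes:
            if p.probe_class == "positive_control" and p.control_label == label:
                return p
        raise KeyError(f"no positive control labeled {label!r} in manifest")

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(p.gene_id for p in self.probes)


@dataclass(frozen=True)
class PanelConfig:
    """Panel layout; defaults reproduce the 770 + 18 = 788 measured genes."""

    n_base_endogenous: int = 730
    n_housekeeping: int = 40
    n_spike_in: int = 18
    n_pos_controls: int = 6
    n_neg_controls: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_base_endogenous", "n_housekeeping", "n_pos_controls", "n_neg_controls"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.n_spike_in < 0:
            raise ConfigurationError("n_spike_in must be nonnegative")
        if self.n_pos_controls > 6:
            raise ConfigurationError("at most 6 positive controls (labels A..F)")


def generate_panel(config: PanelConfig = PanelConfig()) -> PanelManifest:
    """Build a synthetic panel manifest.

    Gene identifiers are deterministic (``GENE0001``.., ``HK01``.., ``SPK01``..,
    ``POS_A``.., ``NEG_01``..); the positive-control ladder is geometric with
    ratio 1/4 from A downwards.
    """
    probes: list[Probe] = []
    probes += [
        Probe(f"GENE{i + 1:04d}", "endogenous") for i in range(config.n_base_endogenous)
    ]
    probes += [Probe(f"HK{i + 1:02d}", "housekeeping") for i in range(config.n_housekeeping)]
    probes += [Probe(f"SPK{i + 1:02d}", "spike_in") for i in range(config.n_spike_in)]
    for i in range(config.n_pos_controls):
        label = POS_LABELS[i]
        conc = POS_LADDER_TOP * POS_LADDER_RATIO**i
        probes.append(Probe(f"POS_{label}", "positive_control", label, conc))
    probes += [Probe(f"NEG_{i + 1:02d}", "negative_control") for i in range(config.n_neg_controls)]
    return PanelManifest(tuple(probes))


# ---------------------------------------------------------------------------
# cohort and counts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleAnnotation:
    """One profiled biopsy with its clinical labels."""

    sample_id: str
    patient_id: str
    timepoint: str  # "pre" | "post"
    response: str  # "CR" | "IR" | "unknown"
    adverse_event: str  # "yes" | "no"
    lesion_count_lmax: int
    lesion_count_week14: int

    def __post_init__(self) -> None:
        if self.timepoint not in ("pre", "post"):
            raise ConfigurationError(f"bad timepoint {self.timepoint!r}")
        if self.response not in ("CR", "IR", "unknown"):
            raise ConfigurationError(f"bad response {self.response!r}")
        if self.adverse_event not in ("yes", "no"):
            raise ConfigurationError(f"bad adverse_event {self.adverse_event!r}")
        if min(self.lesion_count_lmax, self.lesion_count_week14) < 0:
            raise ConfigurationError("lesion counts must be nonnegative")
        if self.response == "CR" and self.lesion_count_week14 != 0:
            raise ConfigurationError("CR requires zero lesions at week 14")
        if self.response == "IR" and self.lesion_count_week14 == 0:
            raise ConfigurationError("IR requires residual lesions at week 14")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-shaped count simulation.

    Defaults follow the trial design: 19 patients, 14 matched pre/post pairs
    (unmatched remainder split 3 pre-only / 2 post-only), 7 complete
    responders, 8 patients with adverse events (enriched among responders),
    70 response-associated genes at |log2FC| = 2 (92% up in CR) and 11
    treatment-responsive genes down-regulated post treatment.
    """

    n_patients: int = 19
    n_matched_pairs: int = 14
    frac_cr: float = 7 / 19
    frac_ae: float = 8 / 19
    n_de_genes_response: int = 70
    n_de_genes_treatment: int = 11
    log2fc_effect: float = 2.0
    frac_up_response: float = 0.92
    nb_dispersion: float = 0.1
    hk_dispersion: float = 0.01
    baseline_mean_range: tuple[float, float] = (4.0, 500.0)
    library_size_cv: float = 0.2
    mean_lmax: float = 9.0
    residual_frac: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0 or self.n_matched_pairs < 0:
            raise ConfigurationError("patient counts must be nonnegative")
        if self.n_matched_pairs > self.n_patients:
            raise ConfigurationError("n_matched_pairs cannot exceed n_patients")
        for name in ("frac_cr", "frac_ae", "frac_up_response"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if min(self.n_de_genes_response, self.n_de_genes_treatment) < 0:
            raise ConfigurationError("planted gene counts must be nonnegative")
        if self.nb_dispersion <= 0 or self.hk_dispersion <= 0:
            raise ConfigurationError("dispersions must be positive")
        lo, hi = self.baseline_mean_range
        if not (0 < lo <= hi):
            raise ConfigurationError("baseline_mean_range must be positive and ordered")
        if not 0.0 <= self.library_size_cv < 1.0:
            raise ConfigurationError("library_size_cv must lie in [0, 1)")
        if self.mean_lmax <= 0:
            raise ConfigurationError("mean_lmax must be positive")
        if not 0.0 <= self.residual_frac <= 1.0:
            raise ConfigurationError("residual_frac must lie in [0, 1]")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth of one simulation, for power/recovery evaluation."""

    response_effects: Mapping[str, float] = field(default_factory=dict)
    treatment_effects: Mapping[str, float] = field(default_factory=dict)
    cr_patients: tuple[str, ...] = ()
    ir_patients: tuple[str, ...] = ()
    ae_patients: tuple[str, ...] = ()
    matched_patients: tuple[str, ...] = ()
    library_factors: Mapping[str, float] = field(default_factory=dict)
    hub_children: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    planted_sets: tuple[str, ...] = ()


def _nb_counts(rng: np.random.Generator, means: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with var = m + dispersion * m^2."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, means * dispersion)
    return rng.poisson(lam)


def simulate_counts(
    manifest: PanelManifest, sim: SimulationConfig
) -> tuple[pd.DataFrame, list[SampleAnnotation], TruthRecord]:
    """Simulate a raw count matrix plus cohort annotations.

    Returns
    -------
    counts
        genes x samples DataFrame of nonnegative integers, rows in manifest
        order.
    annotations
        One :class:`SampleAnnotation` per profiled sample.
    truth
        Planted effects and cohort assignments.

    Counts are negative binomial with mean
    ``library_factor * baseline * 2**(planted log2FC x group indicator)``;
    housekeeping genes carry no group effect and low dispersion; positive
    controls scale with their nominal concentration; negative controls draw
    from a low Poisson background.
    """
    rng = np.random.default_rng(sim.seed)
    patients = [f"P{i + 1:02d}" for i in range(sim.n_patients)]

    # cohort labels
    n_cr = int(round(sim.frac_cr * sim.n_patients))
    cr_set = set(rng.choice(patients, size=n_cr, replace=False)) if n_cr else set()
    n_ae = int(round(sim.frac_ae * sim.n_patients))
    if n_ae and patients:
        # adverse events co-occur with response in the study; weight CR 3:1
        w = np.array([3.0 if p in cr_set else 1.0 for p in patients])
        ae_set = set(rng.choice(patients, size=n_ae, replace=False, p=w / w.sum()))
    else:
        ae_set = set()

    # lesion counts consistent with response labels
    lmax = 1 + rng.poisson(max(sim.mean_lmax - 1.0, 0.0), size=sim.n_patients)
    week14 = np.zeros(sim.n_patients, dtype=int)
    for i, p in enumerate(patients):
        if p not in cr_set:
            week14[i] = 1 + rng.binomial(max(lmax[i] - 1, 0), sim.residual_frac)

    # matched / unmatched design: unmatched remainder alternates pre-only,
    # post-only starting with pre (3 pre-only + 2 post-only at defaults)
    matched = list(rng.choice(patients, size=sim.n_matched_pairs, replace=False))
    matched_set = set(matched)
    unmatched = [p for p in patients if p not in matched_set]
    pre_only = set(unmatched[0::2])
    annotations: list[SampleAnnotation] = []
    sample_cols: list[tuple[str, str]] = []  # (patient, timepoint)
    for i, p in enumerate(patients):
        timepoints = (
            ("pre", "post") if p in matched_set else (("pre",) if p in pre_only else ("post",))
        )
        for tp in timepoints:
            annotations.append(
                SampleAnnotation(
                    sample_id=f"{p}_{tp}",
                    patient_id=p,
                    timepoint=tp,
                    response="CR" if p in cr_set else "IR",
                    adverse_event="yes" if p in ae_set else "no",
                    lesion_count_lmax=int(lmax[i]),
                    lesion_count_week14=int(week14[i]),
                )
            )
            sample_cols.append((p, tp))
    sample_ids = [f"{p}_{tp}" for p, tp in sample_cols]
    n_samples = len(sample_ids)

    # per-sample library factors (lognormal, mean 1, configurable CV)
    if sim.library_size_cv > 0:
        sigma2 = math.log1p(sim.library_size_cv**2)
        lib = rng.lognormal(-sigma2 / 2.0, math.sqrt(sigma2), size=n_samples)
    else:
        lib = np.ones(n_samples)

    # gene baselines
    lo, hi = sim.baseline_mean_range
    genes = manifest.gene_ids
    classes = {p.gene_id: p.probe_class for p in manifest.probes}
    baseline = np.empty(len(genes))
    for i, g in enumerate(genes):
        cls = classes[g]
        if cls in ("endogenous", "spike_in"):
            baseline[i] = math.exp(rng.uniform(math.log(lo), math.log(hi)))
        elif cls == "housekeeping":
            baseline[i] = math.exp(rng.uniform(math.log(200.0), math.log(1000.0)))
        elif cls == "positive_control":
            probe = next(p for p in manifest.probes if p.gene_id == g)
            baseline[i] = POS_COUNT_SCALE * float(probe.nominal_concentration)
        else:  # negative control
            baseline[i] = NEG_BACKGROUND_MEAN

    # planted effects, restricted to genes safely above the detection limit
    posf_mean = POS_COUNT_SCALE * POS_LADDER_TOP * POS_LADDER_RATIO ** (len(POS_LABELS) - 1)
    eligible = [
        g
        for i, g in enumerate(genes)
        if classes[g] in ("endogenous", "spike_in") and baseline[i] >= 4.0 * posf_mean
    ]
    n_planted = sim.n_de_genes_response + sim.n_de_genes_treatment
    if n_planted > len(eligible):
        raise ConfigurationError(
            f"cannot plant {n_planted} effects: only {len(eligible)} eligible genes"
        )
    chosen = list(rng.choice(eligible, size=n_planted, replace=False)) if n_planted else []
    resp_genes = chosen[: sim.n_de_genes_response]
    treat_genes = chosen[sim.n_de_genes_response :]
    for g in resp_genes + treat_genes:
        if classes[g] not in ("endogenous", "spike_in"):
            raise ConfigurationError(f"effect assigned to control probe {g!r}")
    n_up = int(round(sim.frac_up_response * len(resp_genes)))
    response_effects = {
        g: (sim.log2fc_effect if i < n_up else -sim.log2fc_effect)
        for i, g in enumerate(resp_genes)
    }
    treatment_effects = {g: -sim.log2fc_effect for g in treat_genes}

    # mean matrix and draws, one rng pass per probe class for determinism
    means = np.outer(baseline, lib)
    is_cr_col = np.array([p in cr_set for p, _ in sample_cols])
    is_post_col = np.array([tp == "post" for _, tp in sample_cols])
    gene_index = {g: i for i, g in enumerate(genes)}
    for g, eff in response_effects.items():
        means[gene_index[g], is_cr_col] *= 2.0**eff
    for g, eff in treatment_effects.items():
        means[gene_index[g], is_post_col] *= 2.0**eff

    counts = np.zeros(means.shape, dtype=np.int64)
    cls_arr = np.array([classes[g] for g in genes])
    for cls, disp in (
        ("endogenous", sim.nb_dispersion),
        ("spike_in", sim.nb_dispersion),
        ("housekeeping", sim.hk_dispersion),
        ("positive_control", sim.hk_dispersion),
    ):
        rows = cls_arr == cls
        if rows.any():
            counts[rows] = _nb_counts(rng, means[rows], disp)
    neg_rows = cls_arr == "negative_control"
    if neg_rows.any():
        counts[neg_rows] = rng.poisson(NEG_BACKGROUND_MEAN, size=(neg_rows.sum(), n_samples))

    counts_df = pd.DataFrame(counts, index=list(genes), columns=sample_ids)
    counts_df.index.name = "gene_id"
    truth = TruthRecord(
        response_effects=response_effects,
        treatment_effects=treatment_effects,
        cr_patients=tuple(sorted(cr_set)),
        ir_patients=tuple(sorted(set(patients) - cr_set)),
        ae_patients=tuple(sorted(ae_set)),
        matched_patients=tuple(sorted(matched_set)),
        library_factors=dict(zip(sample_ids, lib)),
    )
    return counts_df, annotations, truth


# ---------------------------------------------------------------------------
# lesion counts
# ---------------------------------------------------------------------------


def simulate_lesion_counts(
    n_patients: int,
    mean_lmax: float,
    clearance_prob: float,
    seed: int,
    residual_frac: float = 0.3,
    null: bool = False,
) -> pd.DataFrame:
    """Per-patient (Lmax, week-14) lesion counts.

    Lmax is the maximum lesion count observed during treatment; patients
    clear completely (week 14 = 0) with probability ``clearance_prob`` and
    otherwise retain ``1 + Binomial(Lmax - 1, residual_frac)`` lesions, so
    week14 <= Lmax always holds.

    With ``null=True`` the week-14 count is instead an independent draw from
    the Lmax distribution (no treatment effect); this mode exists for
    calibrating the paired efficacy test and deliberately drops the
    week14 <= Lmax guarantee.
    """
    if mean_lmax <= 0:
        raise ConfigurationError("mean_lmax must be positive")
    if not 0.0 <= clearance_prob <= 1.0:
        raise ConfigurationError("clearance_prob must lie in [0, 1]")
    if n_patients < 0:
        raise ConfigurationError("n_patients must be nonnegative")
    rng = np.random.default_rng(seed)
    lmax = 1 + rng.poisson(max(mean_lmax - 1.0, 0.0), size=n_patients)
    if null:
        week14 = 1 + rng.poisson(max(mean_lmax - 1.0, 0.0), size=n_patients)
    else:
        cleared = rng.random(n_patients) < clearance_prob
        week14 = np.where(
            cleared, 0, 1 + rng.binomial(np.maximum(lmax - 1, 0), residual_frac)
        )
    return pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:02d}" for i in range(n_patients)],
            "lmax": lmax.astype(int),
            "week14": week14.astype(int),
        }
    )


# ---------------------------------------------------------------------------
# background networks
# ---------------------------------------------------------------------------


def generate_background_network(
    n_nodes: int,
    n_directed: int,
    n_undirected: int,
    planted_hubs: Sequence[Mapping[str, int]] = (),
    seed: int = 0,
) -> tuple[BackgroundNetwork, TruthRecord]:
    """Random mixed network with optional planted out-hub drivers.

    Each planted hub is a node wired with exactly ``hub_size`` directed
    out-edges to distinct non-hub nodes (its "regulon"); ``n_directed``
    additional random directed edges originate from non-hub sources, and
    ``n_undirected`` undirected interactions are stored as paired opposite
    directed edges.
    """
    if n_nodes < 2 and (n_directed or n_undirected or planted_hubs):
        raise ConfigurationError("need at least 2 nodes to place edges")
    nodes = [f"N{i + 1:04d}" for i in range(n_nodes)]
    rng = np.random.default_rng(seed)
    hub_sizes = [int(h["hub_size"]) for h in planted_hubs]
    if any(hs >= n_nodes for hs in hub_sizes):
        raise ConfigurationError("hub_size must be smaller than n_nodes")
    hubs = nodes[: len(hub_sizes)]
    non_hubs = nodes[len(hub_sizes) :]

    directed: list[tuple[str, str]] = []
    hub_children: dict[str, tuple[str, ...]] = {}
    for hub, hs in zip(hubs, hub_sizes):
        candidates = [n for n in nodes if n != hub]
        children = tuple(rng.choice(candidates, size=hs, replace=False))
        hub_children[hub] = children
        directed += [(hub, c) for c in children]

    max_random = len(non_hubs) * (n_nodes - 1)
    if n_directed > max_random:
        raise ConfigurationError("too many directed edges for the node count")
    seen = set(directed)
    n_random = 0
    while n_random < n_directed:
        s = non_hubs[rng.integers(len(non_hubs))]
        t = nodes[rng.integers(n_nodes)]
        if s == t or (s, t) in seen:
            continue
        seen.add((s, t))
        directed.append((s, t))
        n_random += 1

    max_und = n_nodes * (n_nodes - 1) // 2
    if n_undirected > max_und:
        raise ConfigurationError("too many undirected edges for the node count")
    undirected: list[tuple[str, str]] = []
    seen_und: set[frozenset[str]] = set()
    while len(undirected) < n_undirected:
        i, j = rng.integers(n_nodes), rng.integers(n_nodes)
        s, t = nodes[i], nodes[j]
        key = frozenset((s, t))
        if s == t or key in seen_und:
            continue
        seen_und.add(key)
        undirected.append((s, t))

    net = BackgroundNetwork.from_mixed(directed, undirected, extra_nodes=nodes)
    return net, TruthRecord(hub_children=hub_children)


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------


def generate_gene_sets(
    universe: Sequence[str],
    n_sets: int = 30,
    set_size_range: tuple[int, int] = (10, 50),
    planted: Mapping[str, Sequence[str]] | None = None,
    seed: int = 0,
) -> dict[str, tuple[str, ...]]:
    """Random gene sets over ``universe`` plus optional planted sets.

    Convenience for exercising over-representation analysis without any
    licensed pathway collection: random sets are null by construction,
    ``planted`` maps set names to explicit member lists (e.g. a planted DE
    gene list) that ORA should flag.
    """
    rng = np.random.default_rng(seed)
    lo, hi = set_size_range
    if not (0 < lo <= hi <= len(universe)):
        raise ConfigurationError("set_size_range infeasible for universe")
    sets: dict[str, tuple[str, ...]] = {}
    for name, members in (planted or {}).items():
        sets[name] = tuple(members)
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        sets[f"RANDOM_SET_{i + 1:03d}"] = tuple(rng.choice(universe, size=size, replace=False))
    return sets
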