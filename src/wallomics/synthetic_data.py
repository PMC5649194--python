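"""Seeded generators emulating every input the pipeline consumes.

Each generator plants known ground truth (moduli, tether parameters, DE
gene sets, gene→phenotype links), records it in a machine-readable truth
dictionary, and is byte-deterministic for a fixed config: recovery tests in
the other modules read the truth record rather than re-deriving it.

The force-curve generators emulate a force-volume experiment — a grid of
Hertz-like approach curves with per-curve moduli drawn from a strain's
stiffness distribution — and lectin-tip retract experiments in which a
fraction of curves carries one or more polymer-tether adhesion fingerprints
(FJC or WLC mechanics, negative force on retract, snap to baseline at a
drawn rupture force).  The expression generator emulates a 5-strain,
3-replicate one-colour array experiment with planted ≥2-fold effects and a
common differentially-expressed core; linked phenotypes are noisy linear
read-outs of planted gene-set means.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .curve_processing import ForceCurve, ForceVolumeMap
from .force_models import ThermalContext, TipGeometry, fjc_extension, fjc_force, hertz_force, wlc_force

__all__ = [
    "ForceSimConfig",
    "ExprSimConfig",
    "strain_presets",
    "force_config_for_strain",
    "gen_force_volume",
    "gen_retract_curves",
    "gen_expression",
    "gen_linked_phenotypes",
]

STRAINS = ("BY4743", "L71", "L62", "L60", "L69")


def strain_presets() -> dict:
    """Per-strain generator presets (measured phenotype means and SDs)."""
    ref = importlib.resources.files("wallomics") / "data" / "strain_presets.yaml"
    return yaml.safe_load(ref.read_text())


@dataclass(frozen=True)
class ForceSimConfig:
    """Parameters of the force-curve generators.

    Defaults correspond to the laboratory strain (BY4743): modal stiffness
    483 ± 61 kPa, 10% specific-event probability, FJC tethers with contour
    lengths 64.8 ± 30 nm and ~60 pN rupture forces.
    """

    grid: tuple = (32, 32)
    E_mean_kPa: float = 483.0
    E_sd_kPa: float = 61.0
    contact_point_nm: float = 120.0
    force_noise_sd_pN: float = 10.0
    tip: TipGeometry = field(default_factory=TipGeometry)
    thermal: ThermalContext = field(default_factory=ThermalContext)
    event_probability: float = 0.10
    events_per_curve: tuple = (1.0,)  # P(1 event), P(2), ... given any event
    polymer_model: str = "FJC"
    Lc_mean_nm: float = 64.8
    Lc_sd_nm: float = 30.0
    stiffness_length_nm: float = 0.5
    rupture_force_mean_pN: float = 60.0
    rupture_force_sd_pN: float = 5.0
    spring_constant_N_per_m: float = 0.015
    approach_speed_um_s: float = 2.0
    step_nm: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.event_probability <= 1.0:
            raise ValueError("event_probability must lie in [0, 1]")
        if abs(sum(self.events_per_curve) - 1.0) > 1e-9 or \
                any(p < 0 for p in self.events_per_curve):
            raise ValueError("events_per_curve must be a probability vector")
        for name in ("E_mean_kPa", "E_sd_kPa", "contact_point_nm", "Lc_mean_nm",
                     "stiffness_length_nm", "rupture_force_mean_pN", "step_nm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.polymer_model not in ("FJC", "WLC"):
            raise ValueError("polymer_model must be 'FJC' or 'WLC'")


def force_config_for_strain(strain: str, **overrides) -> ForceSimConfig:
    """A ForceSimConfig populated from one strain's measured parameters."""
    p = strain_presets()[strain]
    base = ForceSimConfig(
        E_mean_kPa=p["stiffness_kPa"][0], E_sd_kPa=p["stiffness_kPa"][1],
        event_probability=p["adhesion_probability"],
        polymer_model=p["polymer_model"],
        Lc_mean_nm=p["contour_nm"][0], Lc_sd_nm=p["contour_nm"][1],
    )
    return replace(base, **overrides)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      size: int, lower: float = 0.0) -> np.ndarray:
    """Normal draws redrawn until strictly above ``lower``."""
    if sd == 0:
        if mean <= lower:
            raise ValueError("degenerate truncated normal below bound")
        return np.full(size, mean)
    out = rng.normal(mean, sd, size)
    for _ in range(1000):
        bad = out <= lower
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
    raise RuntimeError("truncated-normal redraw failed to converge")


# ---------------------------------------------------------------------------
# Force-volume maps (approach / indentation)
# ---------------------------------------------------------------------------

def gen_force_volume(config: ForceSimConfig) -> tuple[ForceVolumeMap, dict]:
    """Simulate one force-volume map of Hertz-like approach curves.

    Each curve: baseline (noise only) before the contact point, conical
    Hertz force beyond it, per-curve modulus drawn from
    Normal(E_mean, E_sd²) truncated > 0.  Retract traces are event-free
    baselines (indentation experiments use an unfunctionalized tip).
    Returns the map and a truth record with every drawn modulus.
    """
    rng = np.random.default_rng(config.seed)
    rows, cols = config.grid
    n = rows * cols
    s0 = config.contact_point_nm
    sep = np.arange(s0 + 130.0, s0 - 60.0 - 1e-9, -config.step_nm)
    E_true = _truncated_normal(rng, config.E_mean_kPa, config.E_sd_kPa, n)
    curves = []
    for i in range(n):
        delta = np.clip(s0 - sep, 0.0, None)
        force = hertz_force(delta, E_true[i], config.tip)
        if config.force_noise_sd_pN > 0:
            force = force + rng.normal(0.0, config.force_noise_sd_pN, sep.size)
        retract_sep = sep[::-1]
        retract_force = (rng.normal(0.0, config.force_noise_sd_pN, sep.size)
                         if config.force_noise_sd_pN > 0 else np.zeros(sep.size))
        curves.append(ForceCurve(
            approach=np.column_stack([sep, force]),
            retract=np.column_stack([retract_sep, retract_force]),
            meta={"spring_constant_N_per_m": config.spring_constant_N_per_m,
                  "approach_speed_um_s": config.approach_speed_um_s,
                  "grid_index": (i // cols, i % cols)},
        ))
    truth = {
        "E_true_kPa": E_true,
        "contact_point_nm": s0,
        "E_mean_kPa": config.E_mean_kPa,
        "E_sd_kPa": config.E_sd_kPa,
        "seed": config.seed,
    }
    return ForceVolumeMap(rows=rows, cols=cols, curves=curves), truth


# ---------------------------------------------------------------------------
# Retract curves with adhesion fingerprints
# ---------------------------------------------------------------------------

def _rupture_extension(model: str, Lc: float, stiff: float, F_rupture: float,
                       thermal: ThermalContext) -> float:
    """Extension at which the tether force reaches the rupture force."""
    if model == "FJC":
        return float(fjc_extension(F_rupture, stiff, Lc, thermal))
    lo, hi = 1e-9 * Lc, Lc * (1.0 - 1e-9)
    return float(brentq(lambda x: wlc_force(x, stiff, Lc, thermal) - F_rupture, lo, hi))


def _tether_force(model: str, x: np.ndarray, Lc: float, stiff: float,
                  thermal: ThermalContext) -> np.ndarray:
    xc = np.clip(x, 0.0, Lc * (1.0 - 1e-9))
    if model == "FJC":
        return fjc_force(xc, stiff, Lc, thermal)
    return wlc_force(xc, stiff, Lc, thermal)


def gen_retract_curves(config: ForceSimConfig, n_curves: int,
                       ) -> tuple[list, dict]:
    """Simulate lectin-tip retract curves with planted adhesion fingerprints.

    With probability ``event_probability`` a curve carries one or more
    specific tethers (count drawn from ``events_per_curve``); tether contour
    lengths are drawn from Normal(Lc_mean, Lc_sd²) truncated > 0 and sorted
    increasing so successive ruptures occur at increasing distance.  On the
    retract trace the adhesive force is negative (below baseline) and snaps
    to baseline when the drawn rupture force is reached.  Approach traces
    are plain baselines.  Truth records, per curve, the planted tether
    parameters and rupture extensions.
    """
    rng = np.random.default_rng(config.seed)
    thermal = config.thermal
    curves, truth_curves = [], []
    # retraction range generous enough to show the full fingerprint + baseline
    max_sep = max(4.0 * (config.Lc_mean_nm + 3.0 * config.Lc_sd_nm), 150.0)
    sep = np.arange(0.0, max_sep, config.step_nm)
    n_event_choices = np.arange(1, len(config.events_per_curve) + 1)
    for _ in range(n_curves):
        has_event = rng.random() < config.event_probability
        tethers = []
        force = np.zeros_like(sep)
        if has_event:
            n_ev = int(rng.choice(n_event_choices, p=config.events_per_curve))
            Lcs = np.sort(_truncated_normal(rng, config.Lc_mean_nm, config.Lc_sd_nm, n_ev))
            for Lc in Lcs:
                Fr = float(_truncated_normal(rng, config.rupture_force_mean_pN,
                                             config.rupture_force_sd_pN, 1, lower=5.0)[0])
                x_rupt = _rupture_extension(config.polymer_model, Lc,
                                            config.stiffness_length_nm, Fr, thermal)
                active = sep <= x_rupt
                contrib = _tether_force(config.polymer_model, sep[active],
                                        Lc, config.stiffness_length_nm, thermal)
                if contrib.size:
                    # the rupture itself is part of the fingerprint: the last
                    # sampled point of the tether carries the drawn rupture
                    # force (the grid rarely lands exactly on the rupture
                    # extension, and the peak is what the detector reports)
                    contrib[-1] = Fr
                force[active] -= contrib
                tethers.append({"Lc_nm": float(Lc), "rupture_force_pN": Fr,
                                "rupture_extension_nm": x_rupt,
                                "stiffness_length_nm": config.stiffness_length_nm,
                                "model": config.polymer_model})
        if config.force_noise_sd_pN > 0:
            force = force + rng.normal(0.0, config.force_noise_sd_pN, sep.size)
            approach_force = rng.normal(0.0, config.force_noise_sd_pN, sep.size)
        else:
            approach_force = np.zeros(sep.size)
        curves.append(ForceCurve(
            approach=np.column_stack([sep[::-1], approach_force]),
            retract=np.column_stack([sep, force]),
            meta={"spring_constant_N_per_m": config.spring_constant_N_per_m,
                  "approach_speed_um_s": config.approach_speed_um_s},
        ))
        truth_curves.append(tethers)
    truth = {
        "tethers": truth_curves,
        "event_probability": config.event_probability,
        "n_with_events": sum(1 for t in truth_curves if t),
        "polymer_model": config.polymer_model,
        "seed": config.seed,
    }
    return curves, truth


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExprSimConfig:
    """Parameters of the expression-matrix generator.

    Defaults emulate the study design: 5 strains × 3 biological replicates,
    a 71-gene core differential in all four industrial strains versus the
    reference plus strain-specific genes, residual noise 0.25 on the log2
    scale.  Planted effects default to |log2 FC| = 2 (4-fold): the screened
    gene lists hold genes changed by *at least* 2-fold (reported changes run
    from ~1.5- to 20-fold), and planting exactly at the 2-fold screening
    threshold would make each planted gene a coin flip against the FC filter
    rather than a recoverable signal.
    """

    n_genes: int = 2000
    strains: tuple = STRAINS
    reference: str = "BY4743"
    replicates_per_strain: int = 3
    n_de_per_strain: int = 150
    common_core_size: int = 71
    planted_log2fc: float = 2.0
    residual_sd: float = 0.25
    replicate_spots_per_gene: int = 2
    weight_dropout_rate: float = 0.02
    spot_jitter_sd: float = 0.1
    baseline_mean_log2: float = 8.0
    baseline_sd_log2: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_de_per_strain > self.n_genes:
            raise ValueError("n_de_per_strain cannot exceed n_genes")
        if self.common_core_size > self.n_de_per_strain:
            raise ValueError("common_core_size cannot exceed n_de_per_strain")
        if not 0.0 <= self.weight_dropout_rate < 1.0:
            raise ValueError("weight_dropout_rate must lie in [0, 1)")
        if self.reference not in self.strains:
            raise ValueError("reference strain must be one of strains")


def gen_expression(config: ExprSimConfig) -> tuple[pd.DataFrame, pd.DataFrame, dict, dict]:
    """Simulate raw probe intensities with planted differential expression.

    Returns ``(raw, weights, probe_to_gene, truth)``.  ``raw`` is a
    probes × arrays DataFrame of linear-scale intensities (columns named
    ``<strain>_<replicate>``), ``weights`` a same-shape 0/1 spot-quality
    matrix, ``probe_to_gene`` the replicate-spot map.  Truth lists the
    planted DE set per non-reference strain (a shared core of
    ``common_core_size`` genes plus strain-specific genes), signed effects,
    and the array → strain map.
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    arrays = [f"{s}_{r + 1}" for s in config.strains
              for r in range(config.replicates_per_strain)]
    array_to_group = {a: a.rsplit("_", 1)[0] for a in arrays}
    others = [s for s in config.strains if s != config.reference]

    perm = rng.permutation(config.n_genes)
    core = [genes[i] for i in perm[:config.common_core_size]]
    pool = perm[config.common_core_size:]
    n_extra = config.n_de_per_strain - config.common_core_size
    de_sets, offset = {}, 0
    for s in others:
        extra = [genes[i] for i in pool[offset:offset + n_extra]]
        offset += n_extra
        if offset > pool.size:
            raise ValueError("not enough genes for disjoint strain-specific DE sets")
        de_sets[s] = set(core) | set(extra)
    core_signs = {g: float(rng.choice((-1.0, 1.0))) for g in core}
    effects = {s: {g: (core_signs[g] if g in core_signs else float(rng.choice((-1.0, 1.0))))
                   * config.planted_log2fc
                   for g in sorted(de_sets[s])}
               for s in others}

    baseline = rng.normal(config.baseline_mean_log2, config.baseline_sd_log2,
                          config.n_genes)
    gene_idx = {g: i for i, g in enumerate(genes)}
    log2_true = np.tile(baseline[:, None], (1, len(arrays)))
    for j, a in enumerate(arrays):
        s = array_to_group[a]
        if s in effects:
            for g, eff in effects[s].items():
                log2_true[gene_idx[g], j] += eff
    log2_true = log2_true + rng.normal(0.0, config.residual_sd, log2_true.shape)

    probes, probe_to_gene = [], {}
    for g in genes:
        for r in range(config.replicate_spots_per_gene):
            pid = f"{g}_s{r + 1}"
            probes.append(pid)
            probe_to_gene[pid] = g
    spot = np.repeat(log2_true, config.replicate_spots_per_gene, axis=0)
    spot = spot + rng.normal(0.0, config.spot_jitter_sd, spot.shape)
    raw = pd.DataFrame(np.exp2(spot), index=probes, columns=arrays)
    w = (rng.random(spot.shape) >= config.weight_dropout_rate).astype(int)
    # a column must keep at least one good spot
    for j in range(w.shape[1]):
        if w[:, j].sum() == 0:
            w[0, j] = 1
    weights = pd.DataFrame(w, index=probes, columns=arrays)
    truth = {
        "de_sets": {s: set(v) for s, v in de_sets.items()},
        "common_core": set(core),
        "effects": effects,
        "array_to_group": array_to_group,
        "reference": config.reference,
        "seed": config.seed,
    }
    return raw, weights, probe_to_gene, truth


def gen_linked_phenotypes(expression: pd.DataFrame, links: dict,
                          snr: float = 3.0, seed: int = 0,
                          ) -> tuple[pd.DataFrame, dict]:
    """Phenotypes as noisy read-outs of planted gene-set means.

    ``expression`` is a genes × arrays log2 matrix; ``links`` maps each
    phenotype name to ``(gene_list, sign)`` (or just a gene list, sign +1).
    Each phenotype column equals sign × the per-array mean of its linked
    genes' standardized expression plus Gaussian noise with
    SD = signal SD / ``snr``; ``snr=inf`` gives the noise-free limit and
    ``snr=0`` a pure-noise phenotype (unlinked control).  Unknown gene names
    raise.  Returns an arrays × phenotypes block and the truth map.
    """
    rng = np.random.default_rng(seed)
    cols, truth_links = {}, {}
    Z = expression.sub(expression.mean(axis=1), axis=0)
    sd = expression.std(axis=1, ddof=1).replace(0.0, 1.0)
    Z = Z.div(sd, axis=0)
    for pheno, spec in links.items():
        gene_list, sign = (spec if isinstance(spec, tuple) else (spec, 1.0))
        unknown = [g for g in gene_list if g not in expression.index]
        if gene_list and unknown:
            raise ValueError(f"phenotype {pheno!r} links unknown genes: {unknown[:5]}")
        if gene_list:
            signal = sign * Z.loc[list(gene_list)].mean(axis=0).to_numpy()
            sig_sd = float(np.std(signal)) or 1.0
        else:  # unlinked control phenotype
            signal = np.zeros(expression.shape[1])
            sig_sd = 1.0
        if snr == 0 or not gene_list:
            noise_sd = sig_sd if sig_sd > 0 else 1.0
            values = rng.normal(0.0, noise_sd, expression.shape[1])
        elif np.isinf(snr):
            values = signal
        else:
            values = signal + rng.normal(0.0, sig_sd / snr, expression.shape[1])
        cols[pheno] = values
        truth_links[pheno] = {"genes": list(gene_list), "sign": sign}
    block = pd.DataFrame(cols, index=expression.columns)
    return block, {"links": truth_links, "snr": snr, "seed": seed}
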