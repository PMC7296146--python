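"""Synthetic phenotyping experiments with planted ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes: per-plant trait values arranged as genotypes x 2 watering
conditions x carriers x plants x days, with

* a planted *relative drought effect* (RDE) time profile per trait,
  drawn from a small family of archetype shapes (null; early negative
  with recovery; late positive without recovery; transient mid-window;
  negative without recovery) mirroring the profile clusters seen in
  platform experiments;
* a persistent per-genotype deviation around the mean profile (the
  genotype's own drought response), active in proportion to the
  profile — this is what links in-time traits to post-harvest traits;
* day-wise bivariate genotype effects ``(u_C, u_D) ~ N(0, G(day))``
  with an unstructured, possibly time-varying 2x2 covariance, giving the
  genetic correlation between conditions its planted profile;
* carrier effects, per-plant residual noise (variance may differ by
  treatment), and optional gross outliers;
* post-harvest traits whose per-genotype RDE is a linear combination of
  the planted per-genotype deviations of chosen "linked" image traits,
  plus noise.

Planted RDE semantics are on the genotype-mean scale — the estimand of
the downstream analysis — not the per-plant scale.  All randomness flows
from a single integer seed through named substreams so stages can be
re-simulated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import ExperimentDesign
from .io import POSTHARVEST_TRAITS

ARCHETYPE_SHAPES = (
    "null",
    "early_negative_recovering",
    "late_positive_no_recovery",
    "transient_mid",
    "negative_no_recovery",
)


class CovarianceError(ValueError):
    """Planted G(day) is not a valid covariance matrix."""


@dataclass(frozen=True)
class EffectProfileArchetype:
    """Shape of a planted mean-RDE time profile (percent units)."""

    shape: str
    onset_day: int = 0
    peak_day: int = 0
    peak_rde: float = 0.0

    def __post_init__(self):
        if self.shape not in ARCHETYPE_SHAPES:
            raise ValueError(f"unknown archetype shape {self.shape!r}")
        if self.shape == "null":
            if self.peak_rde != 0.0:
                raise ValueError("null archetype must have zero magnitude")
        elif not (1 <= self.onset_day <= self.peak_day):
            raise ValueError("require 1 <= onset_day <= peak_day")


def archetype_effect_profile(archetype: EffectProfileArchetype,
                             design: ExperimentDesign) -> np.ndarray:
    """Per-day planted mean RDE (length n_days, percent).

    Zero before onset, linear rise from onset to the peak magnitude at
    the peak day; ``*_no_recovery`` shapes then hold the peak to the end,
    recovering/transient shapes decay linearly to zero by the last day.
    """
    n = design.n_days
    prof = np.zeros(n)
    if archetype.shape == "null":
        return prof
    if archetype.peak_day > n:
        raise ValueError("peak_day beyond the observation window")
    onset, peak, mag = archetype.onset_day, archetype.peak_day, archetype.peak_rde
    days = np.arange(1, n + 1)
    rise = (days >= onset) & (days <= peak)
    if peak > onset:
        prof[rise] = mag * (days[rise] - onset) / (peak - onset)
    else:
        prof[days >= peak] = mag
    after = days > peak
    if archetype.shape.endswith("no_recovery"):
        prof[after] = mag
    else:  # recovering / transient shapes decay to 0 by the last day
        if n > peak:
            prof[after] = mag * (n - days[after]) / (n - peak)
        prof[days == peak] = mag
    return prof


@dataclass
class TraitScenario:
    """Planted structure of one image-derived trait.

    ``g_matrix`` is either a constant 2x2 covariance of the day-wise
    genotype effects or an (n_days, 2, 2) trajectory.  ``deviation_sd``
    is the standard deviation of the persistent per-genotype RDE
    deviation (percent units) that modulates the planted profile.
    """

    trait_id: str
    baseline: float
    archetype: EffectProfileArchetype
    g_matrix: np.ndarray
    deviation_sd: float = 0.0

    def g_at(self, day_index: int, n_days: int) -> np.ndarray:
        g = np.asarray(self.g_matrix, dtype=float)
        if g.ndim == 2:
            return g
        if g.shape[0] != n_days:
            raise ValueError(f"G trajectory length {g.shape[0]} != n_days {n_days}")
        return g[day_index]


@dataclass
class PostHarvestLink:
    """One post-harvest trait: baseline value, mean RDE shift, and
    weights on the planted per-genotype deviations of linked traits."""

    trait: str
    baseline: float
    base_rde: float
    weights: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.0
    genotype_sd: float = 1.0
    plant_sd: float = 0.5


@dataclass
class SimulationScenario:
    design: ExperimentDesign
    traits: list[TraitScenario]
    carrier_sd: float = 1.0
    plant_sd_control: float = 1.0
    plant_sd_drought: float = 1.0
    outlier_prob: float = 0.0
    outlier_magnitude: float = 0.0
    postharvest: list[PostHarvestLink] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        for v in (self.carrier_sd, self.plant_sd_control, self.plant_sd_drought,
                  self.outlier_magnitude):
            if v < 0:
                raise ValueError("scenario standard deviations must be >= 0")
        if not (0.0 <= self.outlier_prob <= 1.0):
            raise ValueError("outlier_prob must lie in [0, 1]")
        for ts in self.traits:
            g = np.asarray(ts.g_matrix, dtype=float)
            mats = g[None] if g.ndim == 2 else g
            for i, m in enumerate(mats):
                if abs(m[0, 1] - m[1, 0]) > 1e-12:
                    raise CovarianceError(f"trait {ts.trait_id}: G not symmetric")
                if m[0, 0] < 0 or m[1, 1] < 0 or \
                        m[0, 1] ** 2 > m[0, 0] * m[1, 1] + 1e-12:
                    raise CovarianceError(
                        f"trait {ts.trait_id}: invalid covariance at day {i + 1}"
                    )


def _substream(seed: int, *path: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *path]))


def _chol_psd(m: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(m)
    if w.min() < -1e-10 * max(1.0, abs(w.max())):
        raise CovarianceError("covariance has a negative eigenvalue")
    return v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def simulate_experiment(
    scenario: SimulationScenario,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate (plant observations, post-harvest table, ground truth).

    Ground truth records, per trait: the planted mean-RDE profile, the
    per-genotype deviations, and the planted G trajectory; plus the
    post-harvest linkage weights.
    """
    d = scenario.design
    genos = d.genotype_labels()
    n_g, n_days = d.n_genotypes, d.n_days
    n_car, n_pl = d.n_carriers_per_condition, d.n_plants_per_carrier

    truth: dict = {"profiles": {}, "deviations": {}, "g": {},
                   "linked": {}, "seed": scenario.seed}
    frames = []
    for ti, ts in enumerate(scenario.traits):
        prof = archetype_effect_profile(ts.archetype, d)
        activity = prof / ts.archetype.peak_rde if ts.archetype.peak_rde else \
            np.zeros(n_days)
        rng_g = _substream(scenario.seed, 1, ti)   # genotype effects
        rng_n = _substream(scenario.seed, 2, ti)   # carrier/plant noise
        rng_o = _substream(scenario.seed, 3, ti)   # outliers
        rng_d = _substream(scenario.seed, 4, ti)   # persistent deviations

        delta = (rng_d.standard_normal(n_g) * ts.deviation_sd
                 if ts.deviation_sd > 0 else np.zeros(n_g))

        # day-wise bivariate genotype effects
        u = np.empty((n_days, n_g, 2))
        z = rng_g.standard_normal((n_days, n_g, 2))
        gconst = np.asarray(ts.g_matrix, float).ndim == 2
        L = _chol_psd(np.asarray(ts.g_matrix, float)) if gconst else None
        for di in range(n_days):
            Ld = L if gconst else _chol_psd(ts.g_at(di, n_days))
            u[di] = z[di] @ Ld.T

        # genotype-mean values per day: control and drought
        rde_target = prof[:, None] + activity[:, None] * delta[None, :]
        m_c = ts.baseline + u[:, :, 0]
        m_d = (ts.baseline + u[:, :, 1]) * (1.0 + rde_target / 100.0)

        # carrier effects and plant noise, then long-format assembly
        car_eff = rng_n.standard_normal((n_days, n_g, 2, n_car)) * scenario.carrier_sd
        plant_noise = rng_n.standard_normal((n_days, n_g, 2, n_car, n_pl))
        plant_noise[:, :, 0] *= scenario.plant_sd_control
        plant_noise[:, :, 1] *= scenario.plant_sd_drought
        means = np.stack([m_c, m_d], axis=2)  # (days, genos, 2)
        values = (means[:, :, :, None, None] + car_eff[..., None] + plant_noise)
        if scenario.outlier_prob > 0:
            mask = rng_o.random(values.shape) < scenario.outlier_prob
            values = values + mask * scenario.outlier_magnitude

        day_ix, geno_ix, trt_ix, car_ix, pl_ix = np.unravel_index(
            np.arange(values.size), values.shape)
        frames.append(pd.DataFrame({
            "genotype": np.asarray(genos, dtype=object)[geno_ix],
            "treatment": np.asarray(d.treatments, dtype=object)[trt_ix],
            "carrier": np.char.add("c", (car_ix + 1).astype(str)),
            "plant": np.char.add("p", (pl_ix + 1).astype(str)),
            "day": day_ix + 1,
            "trait": ts.trait_id,
            "value": values.ravel(),
        }))
        truth["profiles"][ts.trait_id] = prof.tolist()
        truth["deviations"][ts.trait_id] = dict(zip(genos, delta.tolist()))
        truth["g"][ts.trait_id] = np.asarray(ts.g_matrix, float).tolist()
    obs = pd.concat(frames, ignore_index=True)

    ph_rows = []
    deviations = {t: truth["deviations"][t] for t in truth["deviations"]}
    for pi, link in enumerate(scenario.postharvest):
        if link.trait not in POSTHARVEST_TRAITS:
            raise ValueError(f"unknown post-harvest trait {link.trait!r}")
        rng_p = _substream(scenario.seed, 5, pi)
        b_g = rng_p.standard_normal(n_g) * link.genotype_sd
        eps = rng_p.standard_normal(n_g) * link.noise_sd
        rde_g = np.full(n_g, link.base_rde) + eps
        for tid, w in link.weights.items():
            dev = np.array([deviations[tid][g] for g in genos])
            rde_g = rde_g + w * dev
        mean_c = link.baseline + b_g
        mean_d = mean_c * (1.0 + rde_g / 100.0)
        for t_ix, mean in ((0, mean_c), (1, mean_d)):
            noise = rng_p.standard_normal((n_g, 2)) * link.plant_sd
            for p in range(2):
                ph_rows.append(pd.DataFrame({
                    "genotype": genos,
                    "treatment": d.treatments[t_ix],
                    "plant": f"p{p + 1}",
                    "trait": link.trait,
                    "value": mean + noise[:, p],
                }))
        truth["linked"][link.trait] = dict(link.weights)
        truth.setdefault("postharvest_rde", {})[link.trait] = dict(
            zip(genos, rde_g.tolist()))
    ph = (pd.concat(ph_rows, ignore_index=True)
          if ph_rows else pd.DataFrame(columns=["genotype", "treatment",
                                                "plant", "trait", "value"]))
    return obs, ph, truth


# ---------------------------------------------------------------------------
# bundled demonstration scenario

def _rg_matrix(var_c: float, var_d: float, rg: float) -> np.ndarray:
    return np.array([[var_c, rg * np.sqrt(var_c * var_d)],
                     [rg * np.sqrt(var_c * var_d), var_d]])


#: archetype/genetic-correlation assignments of the demonstration traits.
#: Traits come in six tight families (five effect shapes plus a null
#: family), emulating the redundancy of image pipelines where many traits
#: measure near-identical plant features; the five linked traits each
#: anchor one non-null family, so the joint profile classification can
#: isolate them.
_DEMO_TRAITS: tuple[tuple[str, str, int, int, float, float, float], ...] = (
    # (trait id, shape, onset, peak, magnitude, rg_base, deviation_sd)
    # late positive, no recovery (rg 0.9)
    ("img01", "late_positive_no_recovery", 10, 14, 30.0, 0.9, 5.0),
    ("img09", "late_positive_no_recovery", 10, 14, 26.0, 0.9, 2.0),
    ("img10", "late_positive_no_recovery", 10, 14, 33.0, 0.9, 2.0),
    ("img17", "late_positive_no_recovery", 10, 13, 28.0, 0.9, 2.0),
    # early negative, recovering (rg 0.0)
    ("img02", "early_negative_recovering", 5, 10, -25.0, 0.0, 5.0),
    ("img11", "early_negative_recovering", 5, 10, -22.0, 0.0, 2.0),
    ("img12", "early_negative_recovering", 5, 10, -28.0, 0.0, 2.0),
    ("img18", "early_negative_recovering", 5, 9, -24.0, 0.0, 2.0),
    # negative, no recovery (rg -0.8)
    ("img03", "negative_no_recovery", 6, 14, -30.0, -0.8, 5.0),
    ("img13", "negative_no_recovery", 6, 14, -26.0, -0.8, 2.0),
    ("img14", "negative_no_recovery", 6, 13, -33.0, -0.8, 2.0),
    ("img19", "negative_no_recovery", 6, 14, -35.0, -0.8, 2.0),
    # transient mid-window (rg 0.9)
    ("img04", "transient_mid", 6, 10, 20.0, 0.9, 5.0),
    ("img15", "transient_mid", 6, 10, 24.0, 0.9, 2.0),
    ("img16", "transient_mid", 7, 10, 18.0, 0.9, 2.0),
    ("img20", "transient_mid", 6, 10, 22.0, 0.9, 2.0),
    # early positive, no recovery (rg -0.8)
    ("img05", "late_positive_no_recovery", 6, 10, 35.0, -0.8, 5.0),
    ("img21", "late_positive_no_recovery", 6, 10, 38.0, -0.8, 2.0),
    ("img22", "late_positive_no_recovery", 6, 11, 32.0, -0.8, 2.0),
    ("img23", "late_positive_no_recovery", 6, 10, 30.0, -0.8, 2.0),
    # no drought response (rg 0.9)
    ("img06", "null", 0, 0, 0.0, 0.9, 2.0),
    ("img07", "null", 0, 0, 0.0, 0.9, 2.0),
    ("img08", "null", 0, 0, 0.0, 0.9, 2.0),
    ("img24", "null", 0, 0, 0.0, 0.9, 2.0),
)

#: the traits whose per-genotype deviations drive the post-harvest targets
DEMO_LINKED_TRAITS = ("img01", "img02", "img03", "img04", "img05")


def demo_design() -> ExperimentDesign:
    """Scaled demonstration design: full genotype panel, shorter window."""
    return ExperimentDesign(n_genotypes=97, n_carriers_per_condition=2,
                            n_plants_per_carrier=2, n_days=20,
                            drought_start_day=5, drought_end_day=14)


def demo_scenario(seed: int = 0, design: ExperimentDesign | None = None) -> SimulationScenario:
    """The bundled end-to-end scenario: 24 image traits of which 5 drive
    the post-harvest spike complex and thousand grain weight."""
    d = design if design is not None else demo_design()
    traits = []
    for tid, shape, onset, peak, mag, rg, dev in _DEMO_TRAITS:
        arch = EffectProfileArchetype(shape, onset, peak, mag)
        traits.append(TraitScenario(
            trait_id=tid, baseline=100.0, archetype=arch,
            g_matrix=_rg_matrix(1.0, 1.0, rg), deviation_sd=dev,
        ))
    # each spike-complex member is dominated by one planted driver while
    # sharing all five, so the complex stays internally correlated but
    # every linked trait carries a strong signal for at least one target
    spike_w = {
        "LSm": {"img01": 2.0, "img02": 0.5, "img03": 0.5, "img04": 0.5,
                "img05": 0.5},
        "NSm": {"img01": 0.5, "img02": 2.0, "img03": 0.5, "img04": 0.5,
                "img05": 0.5},
        "NGm": {"img01": 0.5, "img02": 0.5, "img03": 2.0, "img04": 0.5,
                "img05": 0.5},
        "GWm": {"img01": 0.4, "img02": 0.4, "img03": 0.4, "img04": 1.6,
                "img05": 1.6},
    }
    tgw_w = {"img01": 0.8, "img03": 0.8, "img05": 2.0}
    ph = []
    for sym, base in (("LSm", 9.0), ("NSm", 22.0), ("NGm", 20.0), ("GWm", 1.1)):
        ph.append(PostHarvestLink(sym, base, -25.0, spike_w[sym],
                                  noise_sd=2.5, genotype_sd=0.08 * base,
                                  plant_sd=0.05 * base))
    ph.append(PostHarvestLink("TGW", 48.0, -10.0, dict(tgw_w),
                              noise_sd=2.5, genotype_sd=3.0, plant_sd=1.5))
    for sym, base in (("PH", 70.0), ("NTP", 4.0), ("NTT", 6.0), ("LSl", 7.0),
                      ("NSl", 18.0), ("NGl", 16.0), ("GWl", 0.8)):
        ph.append(PostHarvestLink(sym, base, -15.0, {}, noise_sd=8.0,
                                  genotype_sd=0.08 * base, plant_sd=0.05 * base))
    return SimulationScenario(
        design=d, traits=traits, carrier_sd=1.0,
        plant_sd_control=1.0, plant_sd_drought=1.0,
        outlier_prob=0.002, outlier_magnitude=25.0,
        postharvest=ph, seed=seed,
    )
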