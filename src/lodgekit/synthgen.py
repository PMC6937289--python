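"""Seeded synthetic-data generators for every pipeline stage.

Three generators emulate the statistical structure the analysis assumes, so
the whole pipeline is testable without any external download:

* ``gen_field_trial`` — a split-plot nitrogen-management trial: per
  (variety, treatment, internode) group means with a plot-level random
  effect and culm-level noise, invariants enforced by rejection sampling;
* ``gen_two_color_arrays`` — Agilent-44k-like two-channel arrays with an
  intensity-dependent dye bias, spiked differential probes and a truth
  table;
* ``gen_go_universe`` — a gene->GO annotation map with optionally planted
  enriched terms.

All generators are pure functions of (config, seed): the same inputs give
identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from importlib import resources
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TrialConfig",
    "ArrayConfig",
    "default_trial_config",
    "gen_field_trial",
    "gen_two_color_arrays",
    "gen_go_universe",
    "default_dye_bias",
]

@dataclass
class TrialConfig:
    """Configuration of the synthetic split-plot trial.

    ``groups`` maps variety -> treatment -> {plant_height_cm: {mean, se},
    internodes: {index: {trait: {mean, se}}}}.  Plot-level sd is
    se*sqrt(n_replicates); culm-level sd is ``sd_culm_factor`` times that.
    """

    groups: dict
    n_replicates: int = 4
    culms_per_plot: int = 10
    span_cm: float = 5.0
    elastic_load_N: float = 1.0
    sd_culm_factor: float = 2.0

    @classmethod
    def from_dict(cls, data: dict) -> "TrialConfig":
        return cls(
            groups=data["groups"],
            n_replicates=int(data.get("n_replicates", 4)),
            culms_per_plot=int(data.get("culms_per_plot", 10)),
            span_cm=float(data.get("span_cm", 5.0)),
            elastic_load_N=float(data.get("elastic_load_N", 1.0)),
            sd_culm_factor=float(data.get("sd_culm_factor", 2.0)),
        )

    @classmethod
    def from_yaml(cls, path) -> "TrialConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def validate(self) -> None:
        if self.n_replicates < 1 or self.culms_per_plot < 1:
            raise ValueError("n_replicates and culms_per_plot must be >= 1")
        for variety, treatments in self.groups.items():
            for treatment, grp in treatments.items():
                for idx, traits in grp["internodes"].items():
                    d = traits.get("diameter_mm", {}).get("mean")
                    w = traits.get("wall_mm", {}).get("mean")
                    if d is not None and w is not None and not 0 < w <= d / 2:
                        raise ValueError(
                            f"infeasible config for {variety}/{treatment}/I{idx}: "
                            f"mean wall {w} outside (0, diameter/2 = {d / 2}]"
                        )
                    for name, ms in traits.items():
                        if ms["mean"] <= 0 or ms.get("se", 0.0) < 0:
                            raise ValueError(
                                f"invalid mean/se for {variety}/{treatment}/I{idx}/{name}"
                            )


def default_trial_config() -> TrialConfig:
    """Trial defaults transcribed from published two-variety trial tables."""
    text = resources.files("lodgekit").joinpath("data/trial_defaults.yaml").read_text("utf-8")
    return TrialConfig.from_dict(yaml.safe_load(text))


def _sample_positive(rng: np.random.Generator, mean: float, sd: float, max_tries: int = 1000) -> float:
    """Normal draw rejected until positive (trivially so when sd == 0)."""
    if sd == 0:
        return mean
    for _ in range(max_tries):
        x = rng.normal(mean, sd)
        if x > 0:
            return x
    raise RuntimeError(f"rejection sampling failed for mean={mean}, sd={sd}")


def gen_field_trial(config: TrialConfig, seed: int = 0) -> pd.DataFrame:
    """Simulate the split-plot trial as a tidy internode-record table.

    Hierarchy: per trait, a plot effect ~ Normal(0, sd_plot) shifts the group
    mean for the whole replicate plot; each culm's value ~ Normal(plot mean,
    sd_culm).  Geometry invariants (positive values, wall <= diameter/2) are
    enforced by rejection.  Breaking force and the elastic bending test are
    only recorded where they are configured and the sampled internode is at
    least as long as the support span; the deflection is back-computed from
    the sampled elastic modulus so the analysis pipeline can recover it.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    sqrt_n = np.sqrt(config.n_replicates)
    rows = []
    for variety in sorted(config.groups):
        for treatment in sorted(config.groups[variety]):
            grp = config.groups[variety][treatment]
            height = grp.get("plant_height_cm", {"mean": 100.0, "se": 0.0})
            internodes = {int(k): v for k, v in grp["internodes"].items()}
            for rep in range(1, config.n_replicates + 1):
                plot_eff = {
                    (idx, name): rng.normal(0.0, ms.get("se", 0.0) * sqrt_n)
                    for idx, traits in internodes.items()
                    for name, ms in traits.items()
                }
                height_eff = rng.normal(0.0, height.get("se", 0.0) * sqrt_n)
                for culm in range(1, config.culms_per_plot + 1):
                    samples = {}
                    for idx, traits in sorted(internodes.items()):
                        vals = {}
                        for name, ms in traits.items():
                            sd_culm = ms.get("se", 0.0) * sqrt_n * config.sd_culm_factor
                            center = ms["mean"] + plot_eff[(idx, name)]
                            vals[name] = _sample_positive(rng, center, sd_culm)
                        # wall must not exceed the radius: resample the pair
                        tries = 0
                        while vals.get("wall_mm", 0.0) > vals["diameter_mm"] / 2.0:
                            tries += 1
                            if tries > 1000:
                                raise RuntimeError("could not satisfy wall <= diameter/2")
                            for name in ("diameter_mm", "wall_mm"):
                                ms = traits[name]
                                sd_culm = ms.get("se", 0.0) * sqrt_n * config.sd_culm_factor
                                vals[name] = _sample_positive(
                                    rng, ms["mean"] + plot_eff[(idx, name)], sd_culm
                                )
                        samples[idx] = vals

                    culm_height = max(
                        height["mean"] + height_eff,
                        sum(v["length_cm"] for v in samples.values()) + 1.0,
                    )
                    below = 0.0
                    for idx in sorted(samples):
                        vals = samples[idx]
                        dist_tip = culm_height - below
                        below += vals["length_cm"]
                        mech_ok = vals["length_cm"] >= config.span_cm
                        has_bm = "bm_gfcm" in vals
                        row = {
                            "variety": variety,
                            "treatment": treatment,
                            "replicate": rep,
                            "culm": culm,
                            "internode": idx,
                            "length_cm": vals["length_cm"],
                            "diameter_mm": vals["diameter_mm"],
                            "wall_mm": vals["wall_mm"],
                            "dry_mg": vals.get("dry_mg", np.nan),
                            "dist_tip_cm": dist_tip if has_bm else np.nan,
                            "fresh_above_g": (vals["bm_gfcm"] / dist_tip) if has_bm else np.nan,
                            "break_N": vals["break_N"] if mech_ok and "break_N" in vals else np.nan,
                            "span_cm": config.span_cm,
                        }
                        if mech_ok and "e_gpa" in vals:
                            a = vals["diameter_mm"] / 2.0
                            i_mm4 = np.pi * a**4 / 4.0 * (1 - (1 - vals["wall_mm"] / a) ** 4)
                            # invert E = F L^3/(48 delta I) for the deflection
                            f = config.elastic_load_N
                            delta_m = (
                                f
                                * (config.span_cm / 100.0) ** 3
                                / (48.0 * vals["e_gpa"] * 1e9 * i_mm4 * 1e-12)
                            )
                            row["elastic_F_N"] = f
                            row["deflect_cm"] = delta_m * 100.0
                        else:
                            row["elastic_F_N"] = np.nan
                            row["deflect_cm"] = np.nan
                        rows.append(row)
    return pd.DataFrame(rows)


def default_dye_bias(a: np.ndarray) -> np.ndarray:
    """Default intensity-dependent dye bias added to M, magnitude <= 0.6.

    A constant dye offset plus a sinusoid in average log intensity — smooth
    enough for loess to remove, large enough that un-normalized fold-change
    calls are visibly biased.
    """
    return 0.2 + 0.4 * np.sin(np.asarray(a, float) / 2.0)


@dataclass
class ArrayConfig:
    """Configuration of the synthetic two-color array experiment."""

    n_features: int = 45018
    n_up: int = 665
    n_down: int = 713
    effect_low: float = 1.5
    effect_high: float = 3.0
    noise_sd: float = 0.15
    n_replicates: int = 3
    dye_bias: Optional[Callable[[np.ndarray], np.ndarray]] = dc_field(
        default=default_dye_bias
    )
    exact_spikes: Sequence[float] = ()
    frac_bad: float = 0.0

    def validate(self) -> None:
        if self.n_up + self.n_down + len(self.exact_spikes) > self.n_features:
            raise ValueError("more spiked features than probes")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if not 0 <= self.frac_bad < 1:
            raise ValueError("frac_bad must be in [0, 1)")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates")
        if self.effect_low > self.effect_high or self.effect_low <= 0:
            raise ValueError("effect range must satisfy 0 < low <= high")


def gen_two_color_arrays(
    config: ArrayConfig, seed: int = 0
) -> tuple[list[pd.DataFrame], pd.DataFrame]:
    """Simulate replicate two-channel hybridizations plus a truth table.

    Per probe and replicate: latent average log2 intensity A ~ Uniform(6, 14);
    the true log ratio is the spiked log2 fold change (0 for null probes);
    the observed M adds the dye bias evaluated at A and Gaussian noise; the
    channels are reconstructed as Cy5 = 2^(A + M/2), Cy3 = 2^(A - M/2).

    Returns (replicates, truth): each replicate a frame with columns
    probe_id, cy3, cy5, flag; truth with probe_id, true_log2fc, status (up/down/none).
    """
    config.validate()
    rng = np.random.default_rng(seed)
    n = config.n_features
    probe_ids = np.array([f"P{i:06d}" for i in range(1, n + 1)])

    true_m = np.zeros(n)
    status = np.full(n, "none", dtype=object)
    n_exact = len(config.exact_spikes)
    order = rng.permutation(n)
    exact_idx = order[:n_exact]
    up_idx = order[n_exact : n_exact + config.n_up]
    down_idx = order[n_exact + config.n_up : n_exact + config.n_up + config.n_down]
    for i, fc in zip(exact_idx, config.exact_spikes):
        true_m[i] = fc
        status[i] = "up" if fc > 0 else "down"
    true_m[up_idx] = rng.uniform(config.effect_low, config.effect_high, config.n_up)
    status[up_idx] = "up"
    true_m[down_idx] = -rng.uniform(config.effect_low, config.effect_high, config.n_down)
    status[down_idx] = "down"

    truth = pd.DataFrame({"probe_id": probe_ids, "true_log2fc": true_m, "status": status})

    replicates = []
    for _ in range(config.n_replicates):
        a = rng.uniform(6.0, 14.0, n)
        m = true_m + rng.normal(0.0, config.noise_sd, n) if config.noise_sd > 0 else true_m.copy()
        if config.dye_bias is not None:
            m = m + config.dye_bias(a)
        cy5 = 2.0 ** (a + m / 2.0)
        cy3 = 2.0 ** (a - m / 2.0)
        flag = np.where(rng.random(n) < config.frac_bad, "bad", "ok")
        replicates.append(
            pd.DataFrame({"probe_id": probe_ids, "cy3": cy3, "cy5": cy5, "flag": flag})
        )
    return replicates, truth


def gen_go_universe(
    n_genes: int,
    n_terms: int,
    *,
    genes_per_term: int = 10,
    list_size: int = 20,
    enriched: Optional[dict[str, int]] = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Simulate a gene->GO annotation map and a DEG-like gene list.

    Each of ``n_terms`` terms annotates a random sample of
    ``genes_per_term`` genes.  ``enriched`` maps term ids (``GO:0000001``
    style, 1-based) to the exact number of that term's genes to plant in the
    list; remaining list slots are filled uniformly from the other genes.

    Returns (annotation frame with columns gene_id/term, gene list,
    universe).
    """
    if genes_per_term > n_genes:
        raise ValueError("genes_per_term exceeds universe size")
    if list_size > n_genes:
        raise ValueError("list_size exceeds universe size")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(1, n_genes + 1)]
    terms = [f"GO:{i:07d}" for i in range(1, n_terms + 1)]
    ann_rows = []
    members: dict[str, np.ndarray] = {}
    for t in terms:
        idx = rng.choice(n_genes, size=genes_per_term, replace=False)
        members[t] = idx
        ann_rows.extend({"gene_id": genes[i], "term": t} for i in sorted(idx))
    annotation = pd.DataFrame(ann_rows)

    enriched = enriched or {}
    chosen: list[int] = []
    taken: set[int] = set()
    for t, k in enriched.items():
        if t not in members:
            raise ValueError(f"enriched term {t!r} not among generated terms")
        if k > genes_per_term or k > list_size:
            raise ValueError(f"cannot plant {k} genes of term {t!r}")
        pick = rng.choice(members[t], size=k, replace=False)
        for i in pick:
            if i in taken:
                raise ValueError("over-constrained enrichment spec: overlapping plants")
            taken.add(int(i))
            chosen.append(int(i))
    enriched_members = set().union(*(set(members[t]) for t in enriched)) if enriched else set()
    pool = [i for i in range(n_genes) if i not in taken and i not in enriched_members]
    n_fill = list_size - len(chosen)
    if n_fill < 0 or n_fill > len(pool):
        raise ValueError("over-constrained enrichment spec: list cannot be filled")
    chosen.extend(int(i) for i in rng.choice(pool, size=n_fill, replace=False))
    gene_list = [genes[i] for i in sorted(chosen)]
    return annotation, gene_list, genes
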