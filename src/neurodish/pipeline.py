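"""Config-driven orchestration of a synthetic two-genotype experiment.

``run_pipeline`` generates a cohort (per-genotype generator profiles, several
animals, serial recording days), pushes each artifact through the matching
analysis stage, and compares genotypes with the statistics layer:

* MEA spike metrics per well per day  ->  two-way ANOVA genotype x DIV,
* LFP band-power log-ratio timecourses per animal,
* calcium correlated-firing ratio per animal  ->  t-test,
* morphology and puncta endpoints per animal  ->  t-tests.

``reproduce_printed_stats`` recomputes the published two-group t statistics
from the bundled mean/SEM/n table and reports them beside the printed values.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calcium as ca
from . import io as ndio
from . import lfp as lf
from . import mea
from . import morphometry as morpho
from . import synthetic as syn
from .stats import pooled_t, two_way_anova

__all__ = ["CohortConfig", "run_pipeline", "reproduce_printed_stats",
           "load_printed_stats"]

log = logging.getLogger("neurodish")

GENOTYPES = ("wt", "het")


@dataclass
class CohortConfig:
    """Everything needed to simulate and analyze a two-genotype cohort.

    Profiles are per genotype; firing and bursting ramp up linearly over
    the recording days (cultures mature), scaled by ``maturation_ramp``.
    Desk-scale defaults: 6 animals/genotype, 3 recording days, 120 s wells.
    """

    profiles: dict = field(default_factory=lambda: {
        "wt": syn.SimulationProfile(duration_s=120.0),
        "het": syn.SimulationProfile(duration_s=120.0, base_rate_hz=0.5,
                                     burst_rate_per_min=3.0,
                                     synchrony_coupling=0.4),
    })
    calcium_profiles: dict = field(default_factory=lambda: {
        "wt": syn.CalciumSimProfile(n_cells=30, duration_s=300.0,
                                    coupling_per_cell=0.8),
        "het": syn.CalciumSimProfile(n_cells=30, duration_s=300.0,
                                     coupling_per_cell=0.2),
    })
    morphology_params: dict = field(default_factory=lambda: {
        "wt": syn.MorphologyParams(target_total_length_um=848.0,
                                   soma_radius_um=9.0),
        "het": syn.MorphologyParams(target_total_length_um=452.0,
                                    soma_radius_um=8.3),
    })
    puncta_params: dict = field(default_factory=lambda: {
        "wt": syn.PunctaParams(colocalization_fraction=0.7),
        "het": syn.PunctaParams(colocalization_fraction=0.45),
    })
    n_animals: int = 6
    div_days: list = field(default_factory=lambda: [8, 14, 21])
    maturation_ramp: float = 1.0
    include_lfp: bool = True
    raw_fs_hz: float = 2500.0
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValueError("need >= 1 animal per genotype")
        if sorted(self.div_days) != list(self.div_days):
            raise ValueError("div_days must be sorted")

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kw = dict(raw)
        for key, klass in [("profiles", syn.SimulationProfile),
                           ("calcium_profiles", syn.CalciumSimProfile),
                           ("morphology_params", syn.MorphologyParams),
                           ("puncta_params", syn.PunctaParams)]:
            if key in kw:
                kw[key] = {g: klass(**v) for g, v in kw[key].items()}
        return cls(**kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _day_profile(profile: syn.SimulationProfile, day_index: int,
                 n_days: int, ramp: float, seed: int) -> syn.SimulationProfile:
    """Scale firing/bursting by a linear maturation factor and reseed."""
    f = 1.0 if n_days == 1 else 1.0 + ramp * day_index / (n_days - 1)
    return replace(profile, base_rate_hz=profile.base_rate_hz * f,
                   burst_rate_per_min=profile.burst_rate_per_min * f,
                   seed=seed)


def _spawn(seed: int, *key: int) -> int:
    """Deterministic child seed below 2^31 from a root seed and index path."""
    h = hashlib.sha256(("/".join(map(str, (seed,) + key))).encode()).digest()
    return int.from_bytes(h[:4], "little") % (2 ** 31)


def run_pipeline(config: CohortConfig) -> dict:
    """Run the full synthetic experiment; returns the report bundle.

    The bundle holds the per-well activity table, LFP timecourses, per-animal
    endpoints, genotype comparison tests, and a manifest with every parameter
    value and its hash.  When ``config.out_dir`` is set everything is also
    written to disk (CSV/JSON).
    """
    n_days = len(config.div_days)
    activity_rows, lfp_rows, endpoint_rows, failures = [], [], [], []
    for genotype in GENOTYPES:
        for animal in range(config.n_animals):
            aid = f"{genotype}{animal}"
            # --- MEA + LFP per recording day -------------------------------
            lfp_low, lfp_high = [], []
            for di, day in enumerate(config.div_days):
                try:
                    prof = _day_profile(config.profiles[genotype], di, n_days,
                                        config.maturation_ramp,
                                        _spawn(config.seed, 0, animal, di,
                                               GENOTYPES.index(genotype)))
                    spikes, _bursts = syn.simulate_spike_trains(prof)
                    summ = mea.activity_summary(spikes, well_id=aid,
                                                div_day=day)
                    activity_rows.append({
                        "genotype": genotype, "animal": aid, "div_day": day,
                        "wmfr_hz": summ.wmfr_hz, "n_active": summ.n_active,
                        "burst_freq_per_min": summ.burst_freq_per_min,
                        "mean_burst_breadth": summ.mean_burst_breadth,
                        "synchrony_index": summ.synchrony_index})
                    if not config.include_lfp:
                        continue
                    raw = syn.synthesize_raw(
                        spikes, fs_hz=config.raw_fs_hz,
                        oscillations=[(5.0, 10.0 * (1 + di)),
                                      (120.0, 2.0 * (1 + di))],
                        noise_sd_uV=3.0, seed=prof.seed, div_day=day,
                        well_id=aid)
                    series = lf.extract_lfp(raw, cutoff_hz=500.0)
                    lfp_low.append(series)
                    lfp_high.append(series)
                except Exception as exc:  # keep going per the error contract
                    failures.append({"stage": "mea/lfp", "animal": aid,
                                     "div_day": day, "error": str(exc)})
            try:
                bands = [(lf.LOW_BAND, lfp_low), (lf.HIGH_BAND, lfp_high)] \
                    if config.include_lfp else []
                for band, recs in bands:
                    tc = lf.log_power_ratio_timecourse(recs, band)
                    for day, p_uv2, ratio in zip(tc.div_days, tc.power_uV2,
                                                 tc.log10_ratio):
                        lfp_rows.append({
                            "genotype": genotype, "animal": aid,
                            "div_day": day, "f_lo_hz": band[0],
                            "f_hi_hz": band[1], "power_uV2": p_uv2,
                            "log10_ratio": ratio})
            except Exception as exc:
                failures.append({"stage": "lfp_timecourse", "animal": aid,
                                 "div_day": None, "error": str(exc)})
            # --- calcium, morphology, puncta per animal --------------------
            ep = {"genotype": genotype, "animal": aid}
            try:
                cprof = replace(config.calcium_profiles[genotype],
                                seed=_spawn(config.seed, 1, animal,
                                            GENOTYPES.index(genotype)))
                traces, _ = syn.simulate_calcium(cprof)
                dff = ca.delta_f_over_f(traces)
                res = ca.correlated_firing_ratio(dff, seed=cprof.seed)
                ep["correlated_firing_ratio"] = res.ratio
            except Exception as exc:
                failures.append({"stage": "calcium", "animal": aid,
                                 "div_day": None, "error": str(exc)})
            try:
                mseed = _spawn(config.seed, 2, animal,
                               GENOTYPES.index(genotype))
                jit = np.random.default_rng(mseed)
                base = config.morphology_params[genotype]
                # between-animal biological variability: ~10% CV on length,
                # ~5% on soma radius
                mp = replace(
                    base, seed=mseed,
                    target_total_length_um=base.target_total_length_um
                    * float(jit.lognormal(0.0, 0.1)),
                    soma_radius_um=base.soma_radius_um
                    * float(jit.lognormal(0.0, 0.05)))
                m = syn.generate_morphology(mp)
                ms = morpho.morpho_summary(m)
                ep.update({"total_outgrowth_um": ms["total_outgrowth_um"],
                           "soma_area_um2": ms["soma_area_um2"],
                           "n_primary_neurites": ms["n_primary_neurites"]})
                pp = replace(config.puncta_params[genotype],
                             seed=_spawn(config.seed, 3, animal,
                                         GENOTYPES.index(genotype)))
                fld, _truth = syn.generate_puncta(pp)
                _n, dens, _pairs = morpho.colocalize_and_density(
                    fld.pre_points_um, fld.post_points_um,
                    fld.neurite_length_um, max_dist_um=0.5)
                ep["puncta_density_per_50um"] = dens
            except Exception as exc:
                failures.append({"stage": "morphometry", "animal": aid,
                                 "div_day": None, "error": str(exc)})
            endpoint_rows.append(ep)

    activity = pd.DataFrame(activity_rows)
    lfp_table = pd.DataFrame(lfp_rows)
    endpoints = pd.DataFrame(endpoint_rows)

    # --- genotype statistics ----------------------------------------------
    tests = {}
    last_day = config.div_days[-1]
    last = activity[activity["div_day"] == last_day]
    for metric in ["wmfr_hz", "synchrony_index", "burst_freq_per_min"]:
        g1 = last.loc[last["genotype"] == "wt", metric].to_numpy()
        g2 = last.loc[last["genotype"] == "het", metric].to_numpy()
        if g1.size >= 2 and g2.size >= 2:
            r = pooled_t(g1, g2)
            tests[f"t_{metric}_div{last_day}"] = {
                "t": r.value, "df": r.df, "p": r.p_two_sided}
    for metric in ["correlated_firing_ratio", "total_outgrowth_um",
                   "soma_area_um2", "puncta_density_per_50um"]:
        if metric not in endpoints:
            continue
        sub = endpoints.dropna(subset=[metric])
        g1 = sub.loc[sub["genotype"] == "wt", metric].to_numpy()
        g2 = sub.loc[sub["genotype"] == "het", metric].to_numpy()
        if g1.size >= 2 and g2.size >= 2:
            r = pooled_t(g1, g2)
            tests[f"t_{metric}"] = {"t": r.value, "df": r.df,
                                    "p": r.p_two_sided}
    anovas = {}
    if len(config.div_days) >= 2 and len(activity):
        for metric in ["wmfr_hz", "synchrony_index"]:
            tab = activity.rename(columns={metric: "value"})[
                ["value", "genotype", "div_day"]]
            res = two_way_anova(tab, value="value", factor_a="genotype",
                                factor_b="div_day")
            anovas[metric] = {t: {"F": v[0], "df": list(v[1]), "p": v[2]}
                              for t, v in res.terms.items()}

    manifest = {"config": config.to_dict(), "n_failures": len(failures)}
    # hash covers analysis parameters only, not where outputs land
    hashed = {k: v for k, v in manifest["config"].items() if k != "out_dir"}
    manifest_json = json.dumps({"config": hashed,
                                "n_failures": len(failures)},
                               sort_keys=True, default=str)
    manifest["hash"] = hashlib.sha256(manifest_json.encode()).hexdigest()[:16]
    for df in (activity, lfp_table, endpoints):
        if len(df):
            df["manifest_hash"] = manifest["hash"]

    bundle = {"activity": activity, "lfp": lfp_table, "endpoints": endpoints,
              "tests": tests, "anovas": anovas, "failures": failures,
              "manifest": manifest}
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        activity.to_csv(out / "activity.csv", index=False,
                        float_format="%.10g")
        lfp_table.to_csv(out / "lfp_timecourse.csv", index=False,
                         float_format="%.10g")
        endpoints.to_csv(out / "endpoints.csv", index=False,
                         float_format="%.10g")
        ndio.write_json({"tests": tests, "anovas": anovas}, out / "tests.json")
        ndio.write_json(manifest, out / "manifest.json")
        ndio.write_json(failures, out / "failures.json")
        log.info("pipeline outputs written to %s", out)
    return bundle


def load_printed_stats() -> pd.DataFrame:
    """The bundled table of published group summaries (mean/SEM/n per assay)."""
    with resources.files("neurodish").joinpath(
            "data/printed_summary_stats.csv").open() as fh:
        return pd.read_csv(fh)


def reproduce_printed_stats(fixture: pd.DataFrame | None = None) -> pd.DataFrame:
    """Recompute two-group t statistics from published summary rows.

    Each row needs mean/sem/n for both groups and the published t value;
    the output reports the recomputed pooled t (magnitude), the printed one,
    and their relative deviation.  Malformed rows are reported in an
    ``error`` column and do not stop the rest.
    """
    from .stats import GroupSummary

    df = load_printed_stats() if fixture is None else fixture
    out = []
    for _, row in df.iterrows():
        rec = {"label": row.get("label", "?"),
               "printed_t": row.get("printed_t", np.nan)}
        try:
            g1 = GroupSummary(mean=float(row["mean_wt"]),
                              sem=float(row["sem_wt"]), n=int(row["n_wt"]))
            g2 = GroupSummary(mean=float(row["mean_het"]),
                              sem=float(row["sem_het"]), n=int(row["n_het"]))
            r = pooled_t(g1, g2)
            rec.update({"recomputed_t": abs(r.value), "df": r.df,
                        "p_two_sided": r.p_two_sided,
                        "rel_deviation": abs(abs(r.value) - row["printed_t"])
                        / row["printed_t"]})
        except Exception as exc:
            rec["error"] = str(exc)
        out.append(rec)
    return pd.DataFrame(out)
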