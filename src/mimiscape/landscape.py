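"""Fitness-landscape assembly and the end-to-end pipeline.

Joins phenotype-space coordinates (pattern-PCA scores) to field attack
rates, classifies morphs as fitness peaks, valleys or undetermined, scores
ridges between neighbouring peaks, and drives the full synthetic-inputs →
colour-pattern-modelling → visual-model → predation-statistics run.

Annotation rules: a local homozygote whose attack rate is significantly
below the exotic baseline (one-sided Wald test on the log-odds contrast,
α = 0.05) sits on a fitness *peak*; an intermediate (heterozygote) that is
*not* significantly below the exotic baseline falls in a *valley*; an
intermediate that is significantly protected is left undetermined with a
``protected`` flag. Peak height is reported simply as 1 − attack rate.
Annotations are a pure function of (rates, n, thresholds), so a saved
landscape can be reproduced from its own tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import cpm, predation_stats as ps, synthetic_data as sd, visual_model as vm

logger = logging.getLogger(__name__)

__all__ = [
    "FitnessLandscape",
    "RunConfig",
    "annotate_morphs",
    "build_landscape",
    "default_morph_sets",
    "run_pipeline",
]


# --------------------------------------------------------------------------
# Annotation
# --------------------------------------------------------------------------

LOCAL_ROLES = ("hom1", "hom2")


def _one_sided_z(s_a: float, n_a: float, s_b: float, n_b: float) -> float:
    """Wald z for log-odds(a) − log-odds(b); 0.5 added to all cells if any
    count is degenerate (annotation only, never reported as an estimate)."""
    cells = np.array([s_a, n_a - s_a, s_b, n_b - s_b], dtype=float)
    if np.any(cells == 0):
        cells = cells + 0.5
    a1, a0, b1, b0 = cells
    est = np.log(a1 / a0) - np.log(b1 / b0)
    se = np.sqrt(1 / a1 + 1 / a0 + 1 / b1 + 1 / b0)
    return float(est / se)


def annotate_morphs(counts: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Classify morphs as peak / valley / undetermined from attack counts.

    ``counts`` needs columns morph, role, n_recovered, n_attacked; the
    exotic baseline is pooled over all rows with role ``"exotic"``. Local
    homozygotes significantly less attacked than the baseline (one-sided,
    level ``alpha``) are peaks; heterozygotes that fail that test are
    valleys. Without an exotic baseline everything is undetermined.
    """
    out = counts.copy()
    out["rate"] = out["n_attacked"] / out["n_recovered"]
    exotic = out[out["role"] == "exotic"]
    z_crit = stats.norm.ppf(1 - alpha)
    annotations, z_scores, protected = [], [], []
    if exotic.empty:
        logger.warning("no exotic baseline: all annotations undetermined")
        out["annotation"] = "undetermined"
        out["z_vs_exotic"] = np.nan
        out["protected"] = False
    else:
        s_e = float(exotic["n_attacked"].sum())
        n_e = float(exotic["n_recovered"].sum())
        for _, row in out.iterrows():
            if row["role"] == "exotic":
                annotations.append("undetermined")
                z_scores.append(0.0)
                protected.append(False)
                continue
            z = _one_sided_z(row["n_attacked"], row["n_recovered"], s_e, n_e)
            below = z < -z_crit
            if row["role"] in LOCAL_ROLES:
                annotations.append("peak" if below else "undetermined")
                protected.append(below)
            elif row["role"] == "het":
                annotations.append("undetermined" if below else "valley")
                protected.append(below)
            else:
                annotations.append("undetermined")
                protected.append(below)
            z_scores.append(z)
        out["annotation"] = annotations
        out["z_vs_exotic"] = z_scores
        out["protected"] = protected
    lo, hi = [], []
    for _, row in out.iterrows():
        ci = sm_proportion_ci(int(row["n_attacked"]), int(row["n_recovered"]))
        lo.append(ci[0])
        hi.append(ci[1])
    out["ci_low"], out["ci_high"] = lo, hi
    out["height"] = 1.0 - out["rate"]
    return out


def sm_proportion_ci(successes: int, trials: int,
                     alpha: float = 0.05) -> tuple[float, float]:
    """Wilson score interval for an attack rate."""
    from statsmodels.stats.proportion import proportion_confint
    lo, hi = proportion_confint(successes, trials, alpha=alpha, method="wilson")
    return float(lo), float(hi)


@dataclass
class FitnessLandscape:
    """Morph coordinates in phenotype space joined to attack outcomes.

    ``morphs``: one row per morph with role, set id, attack counts/rate,
    Wilson CI, peak/valley/undetermined annotation and the leading PCA
    scores (columns ``pc1..pcK``). ``ridges``: one row per homozygote pair
    with its ridge score (the attack-ratio slope along the segment joining
    the peaks). Tagged with the encoding and observer that produced the
    coordinates.
    """

    morphs: pd.DataFrame
    ridges: pd.DataFrame
    encoding: str
    observer: str
    alpha: float = 0.05

    def to_json(self) -> str:
        payload = {
            "encoding": self.encoding,
            "observer": self.observer,
            "alpha": self.alpha,
            "morphs": json.loads(self.morphs.to_json(orient="records")),
            "ridges": json.loads(self.ridges.to_json(orient="records")),
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @property
    def peaks(self) -> list[str]:
        return list(self.morphs.loc[self.morphs["annotation"] == "peak", "morph"])

    @property
    def valleys(self) -> list[str]:
        return list(self.morphs.loc[self.morphs["annotation"] == "valley", "morph"])


def _ridge_scores(records: list[ps.RatioRecord], pair_of: dict[str, str],
                  encoding: str, observer: str) -> pd.DataFrame:
    """Attack-ratio slope vs het-homD per homozygote pair.

    Pairs with at least two ratio records get the OLS slope; a single
    record gives the secant slope through the ideal protection point
    (distance 0, ratio 1).
    """
    by_pair: dict[str, list[ps.RatioRecord]] = {}
    for rec in records:
        by_pair.setdefault(pair_of[rec.set_id], []).append(rec)
    rows = []
    for pair, recs in by_pair.items():
        ds = [r.distance(encoding, observer, "het_homD") for r in recs]
        hh = float(np.mean(
            [r.distance(encoding, observer, "hom_hom") for r in recs]))
        if len(recs) >= 2 and np.ptp(ds) > 0:
            slope = float(np.polyfit(ds, [r.ratio for r in recs], 1)[0])
        else:
            slope = float((recs[0].ratio - 1.0) / ds[0]) if ds[0] > 0 else np.nan
        rows.append({"pair": pair, "n_records": len(recs),
                     "ridge_score": slope, "hom_hom_distance": hh})
    return pd.DataFrame(rows).sort_values("pair", ignore_index=True)


def build_landscape(scores: pd.DataFrame, counts: pd.DataFrame,
                    ratio_records: list[ps.RatioRecord] | None = None,
                    pair_of: dict[str, str] | None = None,
                    encoding: str = "binary", observer: str = "",
                    alpha: float = 0.05, n_components: int = 8,
                    ) -> FitnessLandscape:
    """Assemble a fitness landscape from PCA scores and attack counts.

    ``scores``: pattern-PCA scores indexed by morph id. ``counts``: one
    row per morph (morph, role, set_id, n_recovered, n_attacked). Morph
    ids must agree between the two.
    """
    annotated = annotate_morphs(counts, alpha=alpha)
    k = min(n_components, scores.shape[1])
    coord_cols = {f"pc{i + 1}": scores.iloc[:, i] for i in range(k)}
    coords = pd.DataFrame(coord_cols, index=scores.index.astype(str))
    missing = set(annotated["morph"].astype(str)) - set(coords.index)
    if missing:
        raise ValueError(f"morphs without coordinates: {sorted(missing)}")
    morphs = annotated.merge(coords, left_on="morph", right_index=True,
                             how="left")
    if ratio_records and pair_of:
        ridges = _ridge_scores(ratio_records, pair_of, encoding, observer)
    else:
        ridges = pd.DataFrame(
            columns=["pair", "n_records", "ridge_score", "hom_hom_distance"])
    return FitnessLandscape(morphs=morphs, ridges=ridges, encoding=encoding,
                            observer=observer, alpha=alpha)


# --------------------------------------------------------------------------
# Demo morph sets
# --------------------------------------------------------------------------

def default_morph_sets(n_sets: int = 5) -> list[dict]:
    """Parametric morph sets emulating the field design.

    Each set holds a dominant homozygote (elongated yellow band), a
    recessive homozygote (orange patch), and a heterozygote blended with a
    dominance coefficient that decreases across sets — so the het-homD
    distance grows from set to set, like morph sets sorted from most to
    least similar. The exotic morph carries a white patch pattern absent
    from every local set.
    """
    if not 1 <= n_sets <= 8:
        raise ValueError("supported range: 1-8 sets")
    sets = []
    d_values = np.linspace(0.9, 0.35, n_sets)
    for i in range(n_sets):
        shift = 0.02 * i
        hom1 = sd.MorphSpec(
            name=f"set{i + 1}_hom1",
            pattern_elements=[sd.PatchSpec(
                "ellipse", (0.5, 0.38 + shift), (0.28, 0.075), "yellow")],
        )
        hom2 = sd.MorphSpec(
            name=f"set{i + 1}_hom2",
            pattern_elements=[sd.PatchSpec(
                "ellipse", (0.5, 0.62 - shift), (0.22, 0.14), "orange")],
        )
        sets.append({
            "set_id": f"set{i + 1}",
            "hom1": hom1,
            "hom2": hom2,
            "d": float(d_values[i]),
            "exotic": sd.MorphSpec(
                name=f"set{i + 1}_exotic",
                pattern_elements=[
                    sd.PatchSpec("ellipse", (0.38, 0.5), (0.12, 0.10), "white"),
                    sd.PatchSpec("ellipse", (0.62, 0.5), (0.12, 0.10), "orange"),
                ],
            ),
        })
    return sets


# --------------------------------------------------------------------------
# Pipeline
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration of one end-to-end run.

    With no input paths the synthetic generator supplies everything. The
    observers/encodings lists control which perceptual spaces are fitted;
    the landscape coordinates default to the QC PCA under the blue-tit
    (UV-vision) observer, with binary coordinates always co-emitted.
    """

    seed: int = 0
    output_dir: str | None = None
    n_sets: int = 5
    resolution: tuple[int, int] = (64, 64)
    noise_sd: float = 0.02
    groups_per_site: int = 200
    observers: tuple[str, ...] = ("blue_tit", "peafowl", "human")
    encodings: tuple[str, ...] = ("binary", "qc")
    n_components: int = 8
    attack_prob: dict[str, float] = field(
        default_factory=lambda: dict(sd.DEFAULT_ATTACK_PROB))
    recovery_prob: float = sd.DEFAULT_RECOVERY_PROB
    landscape_encoding: str = "qc"
    landscape_observer: str = "blue_tit"
    predation_csv: str | None = None
    make_plots: bool = True
    alpha: float = 0.05

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        cfg.resolution = tuple(cfg.resolution)
        cfg.observers = tuple(cfg.observers)
        cfg.encodings = tuple(cfg.encodings)
        return cfg


def _stage(name: str):
    """Decorator-free stage guard: re-raise with a stage-tagged message."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    return _Ctx()


def _site_layout(n_sets: int) -> dict[str, str]:
    """Eight sites combined into site-groups; the first three sets are each
    tested at two sites (mirroring sets tested at two localities)."""
    sites: dict[str, str] = {}
    s = 1
    for i in range(n_sets):
        reps = 2 if (i < 3 and n_sets >= 5) else 1
        for _ in range(reps):
            sites[f"site{s}"] = f"set{i + 1}"
            s += 1
    return sites


def run_pipeline(config: RunConfig) -> dict:
    """Run synthetic inputs → CPM → visual model → statistics → landscape.

    Returns a bundle dict with every intermediate object; when
    ``config.output_dir`` is set, also writes tidy CSVs, landscape.json, a
    run log and diagnostic plots. Deterministic under a fixed seed.
    """
    import importlib.metadata as _md
    from pathlib import Path

    rng = np.random.default_rng(config.seed)
    bundle: dict = {"config": config}

    with _stage("synthetic_data"):
        morph_sets = default_morph_sets(config.n_sets)
        images: dict[str, cpm.WingImage] = {}
        roles_of: dict[str, str] = {}
        set_of: dict[str, str] = {}
        for ms in morph_sets:
            seeds = rng.integers(0, 2 ** 31 - 1, size=4)
            renders = {
                "hom1": sd.render_morph(ms["hom1"], config.resolution,
                                        config.noise_sd, int(seeds[0])),
                "hom2": sd.render_morph(ms["hom2"], config.resolution,
                                        config.noise_sd, int(seeds[1])),
                "het": sd.blend_heterozygote(
                    sd.DominanceBlend(ms["hom1"], ms["hom2"], ms["d"]),
                    config.resolution, config.noise_sd, int(seeds[2]),
                    name=f"{ms['set_id']}_het"),
                "exotic": sd.render_morph(ms["exotic"], config.resolution,
                                          config.noise_sd, int(seeds[3])),
            }
            for role, img in renders.items():
                images[img.specimen_id] = img
                roles_of[img.specimen_id] = role
                set_of[img.specimen_id] = ms["set_id"]
        spectra = sd.make_reflectance_set()
        illuminant = vm.flat_illuminant()

    with _stage("cpm"):
        cmaps = [cpm.categorize_pixels(img) for img in images.values()]
        template, _ = cpm.build_average_template(cmaps)
        aligned = {c.specimen_id: cpm.align_to_template(c, template)
                   for c in cmaps}
        ids = sorted(aligned)
        binary_features = pd.DataFrame(
            np.stack([cpm.binary_encode(aligned[i]) for i in ids]), index=ids)
        pcas: dict[tuple[str, str], cpm.PatternPCA] = {
            ("binary", ""): cpm.fit_pattern_pca(
                binary_features, config.n_components, encoding="binary"),
        }

    with _stage("visual_model"):
        observers = {name: vm.observer_preset(name) for name in config.observers}
        if "qc" in config.encodings:
            for name, obs in observers.items():
                catches = vm.class_quantum_catches(spectra, illuminant, obs)
                feats = pd.DataFrame(
                    np.stack([vm.qc_encode(aligned[i], catches) for i in ids]),
                    index=ids)
                pcas[("qc", name)] = cpm.fit_pattern_pca(
                    feats, config.n_components, encoding="quantum_catch")

    with _stage("distances"):
        distance_rows = []
        dist_by_set: dict[str, dict[tuple[str, str], cpm.DistanceSet]] = {}
        for ms in morph_sets:
            sid = ms["set_id"]
            per_key = {}
            for (enc, obs_name), pca in pcas.items():
                dset = cpm.distance_set(pca, f"{sid}_het", f"{sid}_hom1",
                                        f"{sid}_hom2", observer=obs_name)
                per_key[(enc, obs_name)] = dset
                distance_rows.append({
                    "set_id": sid, "encoding": enc, "observer": obs_name,
                    "het_homD": dset.het_homD, "het_homR": dset.het_homR,
                    "hom_hom": dset.hom_hom,
                })
            dist_by_set[sid] = per_key
        distances = pd.DataFrame(distance_rows)

    with _stage("predation"):
        if config.predation_csv is not None:
            table = sd.read_predation_csv(config.predation_csv)
        else:
            design = sd.ExperimentDesign(
                sites=_site_layout(config.n_sets),
                groups_per_site=config.groups_per_site,
                attack_prob=dict(config.attack_prob),
                recovery_prob=config.recovery_prob,
                seed=int(rng.integers(0, 2 ** 31 - 1)),
            )
            table = sd.simulate_predation(design)

    with _stage("predation_stats"):
        summary = ps.summarize_attacks(table)
        chi2, dof, chi_p = ps.chisq_site_homogeneity(
            ps.palatable_site_counts(table))
        pooled_glm = ps.fit_attack_glm(table, reference_role="exotic")
        set_map = {ms["set_id"]: [ms["set_id"]] for ms in morph_sets}
        set_glms = ps.per_set_glm(table, set_map, reference_role="hom1")

        records: list[ps.RatioRecord] = []
        for ms in morph_sets:
            sid = ms["set_id"]
            grp = summary.per_group
            het_n = grp.loc[(grp["role"] == "het") & (grp["site_group"] == sid),
                            "n_attacked"]
            hom_n = grp.loc[(grp["role"] == "hom1") & (grp["site_group"] == sid),
                            "n_attacked"]
            ratio, corrected = ps.attack_ratio(int(het_n.sum()), int(hom_n.sum()))
            records.append(ps.RatioRecord(
                set_id=sid, locality=sid, ratio=ratio,
                distances=dist_by_set[sid], corrected=corrected))

        regressions = {}
        for key in pcas:
            enc, obs_name = key
            for which in ("het_homD", "hom_hom"):
                try:
                    regressions[(enc, obs_name, which)] = \
                        ps.regress_ratio_on_distance(records, enc, obs_name,
                                                     which=which)
                except ValueError as err:
                    logger.warning("regression %s skipped: %s", key, err)

        lkey = (config.landscape_encoding,
                config.landscape_observer if config.landscape_encoding == "qc"
                else "")
        het_rows = []
        for ms in morph_sets:
            sid = ms["set_id"]
            grp = summary.per_group
            sel = (grp["role"] == "het") & (grp["site_group"] == sid)
            dset = dist_by_set[sid][lkey]
            het_rows.append({
                "set_id": sid,
                "n_recovered": int(grp.loc[sel, "n_recovered"].sum()),
                "n_attacked": int(grp.loc[sel, "n_attacked"].sum()),
                "het_homD": dset.het_homD,
                "het_homR": dset.het_homR,
            })
        model_cmp = ps.compare_distance_models(pd.DataFrame(het_rows))

    with _stage("landscape"):
        counts_rows = []
        for ms in morph_sets:
            sid = ms["set_id"]
            grp = summary.per_group
            for role in ("hom1", "hom2", "het", "exotic"):
                sel = (grp["role"] == role) & (grp["site_group"] == sid)
                counts_rows.append({
                    "morph": f"{sid}_{role}", "role": role, "set_id": sid,
                    "n_recovered": int(grp.loc[sel, "n_recovered"].sum()),
                    "n_attacked": int(grp.loc[sel, "n_attacked"].sum()),
                })
        counts = pd.DataFrame(counts_rows)
        pair_of = {ms["set_id"]: f"{ms['set_id']}_hom1|{ms['set_id']}_hom2"
                   for ms in morph_sets}
        landscapes = {
            key: build_landscape(
                pca.scores, counts, records, pair_of,
                encoding=key[0], observer=key[1], alpha=config.alpha,
                n_components=config.n_components)
            for key, pca in pcas.items()
        }
        landscape = landscapes[lkey]

    bundle.update(
        images=images, template=template, aligned=aligned, pcas=pcas,
        distances=distances, table=table, summary=summary,
        chisq=(chi2, dof, chi_p), pooled_glm=pooled_glm, set_glms=set_glms,
        ratio_records=records, regressions=regressions, model_cmp=model_cmp,
        landscapes=landscapes, landscape=landscape,
    )

    if config.output_dir is not None:
        with _stage("outputs"):
            out = Path(config.output_dir)
            out.mkdir(parents=True, exist_ok=True)
            sd.write_predation_csv(table, out / "predation.csv")
            distances.to_csv(out / "distances.csv", index=False)
            summary.per_group.to_csv(out / "attacks_per_group.csv", index=False)
            summary.per_role.to_csv(out / "attacks_per_role.csv", index=False)
            pooled_glm.contrasts.to_csv(out / "glm_contrasts.csv", index=False)
            pd.concat(
                [g.contrasts.assign(set_id=sid) for sid, g in set_glms.items()],
                ignore_index=True,
            ).to_csv(out / "per_set_glm_contrasts.csv", index=False)
            pd.DataFrame([
                {"encoding": e, "observer": o, "distance": w,
                 "slope": r.slope, "intercept": r.intercept,
                 "r_squared": r.r_squared, "adj_r_squared": r.adj_r_squared,
                 "f_statistic": r.f_statistic, "p_value": r.p_value, "n": r.n}
                for (e, o, w), r in regressions.items()
            ]).to_csv(out / "ratio_regressions.csv", index=False)
            model_cmp.table.to_csv(out / "model_comparison.csv", index=False)
            (out / "landscape.json").write_text(landscape.to_json())
            for key, pca in pcas.items():
                tag = key[0] if key[0] == "binary" else f"qc_{key[1]}"
                pca.scores.to_csv(out / f"scores_{tag}.csv")
            try:
                version = _md.version("mimiscape")
            except _md.PackageNotFoundError:
                version = "unknown"
            log = {
                "seed": config.seed,
                "mimiscape": version,
                "numpy": np.__version__,
                "pandas": pd.__version__,
                "n_sets": config.n_sets,
                "groups_per_site": config.groups_per_site,
                "observers": list(config.observers),
                "encodings": list(config.encodings),
            }
            (out / "run_log.json").write_text(json.dumps(log, indent=2,
                                                         sort_keys=True))
            if config.make_plots:
                _diagnostic_plots(out, pcas, records, regressions)
    return bundle


def _diagnostic_plots(out, pcas, records, regressions) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for key, pca in pcas.items():
        if key[0] != "binary":
            continue
        sc = pca.scores
        ax.scatter(sc.iloc[:, 0], sc.iloc[:, 1], s=18)
        for sid, row in sc.iterrows():
            ax.annotate(str(sid), (row.iloc[0], row.iloc[1]), fontsize=5)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.set_title("Binary pattern PCA scores")
    fig.tight_layout()
    fig.savefig(out / "scores_scatter.png", dpi=120)
    plt.close(fig)

    keys = [k for k in regressions if k[2] == "het_homD"]
    if keys:
        fig, axes = plt.subplots(1, len(keys), figsize=(3.2 * len(keys), 3.2),
                                 squeeze=False)
        for ax, key in zip(axes[0], keys):
            enc, obs_name, which = key
            x = [r.distance(enc, obs_name, which) for r in records]
            y = [r.ratio for r in records]
            reg = regressions[key]
            ax.scatter(x, y, s=20)
            xs = np.linspace(min(x), max(x), 20)
            ax.plot(xs, reg.intercept + reg.slope * xs, "--")
            ax.axhline(1.0, lw=0.8)
            ax.set_title(f"{enc} {obs_name}".strip(), fontsize=8)
            ax.set_xlabel("het-homD distance", fontsize=7)
            ax.set_ylabel("attack ratio het/hom1", fontsize=7)
        fig.tight_layout()
        fig.savefig(out / "ratio_vs_distance.png", dpi=120)
        plt.close(fig)
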