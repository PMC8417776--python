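"""End-to-end orchestration: synthesize cohorts, train, quantify, compare.

Each command is a pure function of (config, seed, inputs on disk): rerunning
with the same config reproduces the same CSVs byte for byte.  The CLI in
:mod:`lesionquant.cli` is a thin wrapper over these functions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import defaults, stats
from .patches import PatchClassifier, build_grid, features_for_patches, fit_classifier, predict_probs
from .quantify import (
    LesionMask,
    LikelihoodMap,
    NoTissueError,
    QuantResult,
    accumulate_map,
    quantify,
    threshold_map,
)
from .synthetic import (
    ArmSpec,
    FractionDistribution,
    GroundTruth,
    LabeledPatchSet,
    PointMass,
    ScaledBeta,
    StarvedClassError,
    SyntheticSlideSpec,
    generate_cohort,
    eligible_patch_origins,
    write_cohort,
)
from .tissue import MorphologyParams, TissueMask, extract_tissue

__all__ = [
    "RunConfig",
    "ExperimentReport",
    "quantify_slide",
    "run_synth",
    "run_train",
    "run_quantify",
    "run_compare",
    "run_report",
    "incidence_table",
]

log = logging.getLogger("lesionquant")


@dataclass
class RunConfig:
    """Configuration of a pipeline run; YAML-serializable.

    Relative paths in a YAML file are resolved against the file's directory.
    """

    outdir: Path = Path("out")
    seed: int = 0
    patch_size: int = defaults.PATCH_SIZE
    stride: int = defaults.STRIDE
    min_tissue_frac: float = defaults.MIN_TISSUE_FRAC
    theta: float = defaults.THRESHOLD
    reg_strength: float = defaults.REG_STRENGTH
    n_train_patches_per_class: int = 200
    train_purity: float = 0.9
    min_component_area_px: int = defaults.MIN_COMPONENT_AREA_PX
    morphology: MorphologyParams = field(default_factory=MorphologyParams)
    slide: dict[str, Any] = field(default_factory=dict)
    arms: list[dict[str, Any]] = field(default_factory=list)
    manifest: Path | None = None
    classifier_path: Path | None = None
    results_path: Path | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.theta <= 1:
            raise ValueError("theta must be in [0, 1]")
        self.outdir = Path(self.outdir)
        for name in ("manifest", "classifier_path", "results_path"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, Path(v))
        if self.classifier_path is None:
            self.classifier_path = self.outdir / "classifier.json"
        if self.results_path is None:
            self.results_path = self.outdir / "results.csv"

    # -- (de)serialization -------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        doc = yaml.safe_load(path.read_text()) or {}
        base = path.parent
        morph = MorphologyParams(**doc.pop("morphology", {}))
        kwargs = {k: v for k, v in doc.items()}
        cfg = cls(**{**kwargs, "morphology": morph})
        for name in ("outdir", "manifest", "classifier_path", "results_path"):
            v = getattr(cfg, name)
            if v is not None and not Path(v).is_absolute():
                setattr(cfg, name, base / v)
        return cfg

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, Path):
                d[k] = str(v)
        return d

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]

    # -- pieces ------------------------------------------------------------

    def slide_spec(self) -> SyntheticSlideSpec:
        return SyntheticSlideSpec(**self.slide)

    def arm_specs(self) -> list[ArmSpec]:
        base = self.slide_spec()
        out = []
        for arm in self.arms:
            out.append(
                ArmSpec(
                    name=str(arm["name"]),
                    n_animals=int(arm["n_animals"]),
                    fraction_distribution=_distribution_from_dict(arm["distribution"]),
                    base_spec=base,
                )
            )
        return out


def _distribution_from_dict(doc: dict[str, Any]) -> FractionDistribution:
    kind = doc.get("kind", "beta")
    if kind == "point":
        return PointMass(float(doc.get("value", 0.0)))
    if kind == "beta":
        return ScaledBeta(
            mean_fraction=float(doc["mean"]),
            concentration=float(doc.get("concentration", 50.0)),
            upper=float(doc.get("upper", 1.0)),
        )
    raise ValueError(f"unknown fraction distribution kind {kind!r}")


@dataclass(frozen=True)
class ExperimentReport:
    """Tabulated outcome of an arm comparison plus provenance."""

    per_slide: pd.DataFrame
    arms: pd.DataFrame
    contrasts: pd.DataFrame
    provenance: dict[str, Any]


# --------------------------------------------------------------------------
# per-slide end-to-end quantification
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SlideOutputs:
    tissue: TissueMask
    likelihood: LikelihoodMap
    lesion: LesionMask
    result: QuantResult


def quantify_slide(
    image: np.ndarray,
    clf: PatchClassifier,
    slide_id: str = "",
    stride: int = defaults.STRIDE,
    min_tissue_frac: float = defaults.MIN_TISSUE_FRAC,
    theta: float = defaults.THRESHOLD,
    morphology: MorphologyParams | None = None,
    min_component_area_px: int = defaults.MIN_COMPONENT_AREA_PX,
) -> SlideOutputs:
    """Tissue extraction → patch probabilities → likelihood map → ratio."""
    tissue = extract_tissue(image, morphology)
    if tissue.area_px == 0:
        raise NoTissueError(f"slide {slide_id or '<unnamed>'}: no tissue detected")
    grid = build_grid(
        image.shape[:2], tissue, clf.patch_size, stride, min_tissue_frac
    )
    probs = predict_probs(grid, image, clf)
    lmap = accumulate_map(image.shape[:2], grid, probs)
    lesion = threshold_map(lmap, tissue, theta)
    result = quantify(
        tissue,
        lesion,
        slide_id=slide_id,
        theta=theta,
        min_component_area_px=min_component_area_px,
    )
    return SlideOutputs(tissue=tissue, likelihood=lmap, lesion=lesion, result=result)


# --------------------------------------------------------------------------
# commands
# --------------------------------------------------------------------------


def run_synth(config: RunConfig) -> Path:
    """Generate the configured cohort; returns the manifest path."""
    if not config.arms:
        raise ValueError("config defines no arms to synthesize")
    cohort_dir = config.outdir / "cohort"
    log.info("synth: config %s seed %d -> %s", config.config_hash(), config.seed, cohort_dir)
    cohort = generate_cohort(config.arm_specs(), seed=config.seed)
    write_cohort(cohort, cohort_dir)
    return cohort_dir / "manifest.csv"


def _load_manifest(config: RunConfig) -> tuple[pd.DataFrame, Path]:
    manifest_path = config.manifest or config.outdir / "cohort" / "manifest.csv"
    if not Path(manifest_path).exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    return pd.read_csv(manifest_path), Path(manifest_path).parent


def _read_mask(path: Path) -> np.ndarray:
    return np.asarray(iio.imread(path)) > 127


def run_train(config: RunConfig) -> PatchClassifier:
    """Sample labeled patches across the manifest's slides and fit.

    Per-class quotas are spread over the slides that can supply each label;
    a class that cannot be filled raises :class:`StarvedClassError`.
    """
    manifest, base = _load_manifest(config)
    if "lesion_mask_path" not in manifest.columns:
        raise ValueError("manifest lacks ground-truth mask columns; cannot train")
    rng = np.random.default_rng(config.seed)
    p = config.patch_size
    need = {0: config.n_train_patches_per_class, 1: config.n_train_patches_per_class}
    got: dict[int, list[np.ndarray]] = {0: [], 1: []}
    for _, row in manifest.iterrows():
        if need[0] <= 0 and need[1] <= 0:
            break
        image = np.asarray(iio.imread(base / row["image_path"]))
        gt = GroundTruth.from_masks(
            _read_mask(base / row["tissue_mask_path"]),
            _read_mask(base / row["lesion_mask_path"]),
        )
        for label in (0, 1):
            if need[label] <= 0:
                continue
            rr, cc = eligible_patch_origins(gt, p, config.train_purity, label)
            if rr.size == 0:
                continue
            take = min(need[label], rr.size)
            pick = rng.choice(rr.size, size=take, replace=False)
            for i in pick:
                r, c = int(rr[i]), int(cc[i])
                got[label].append(image[r : r + p, c : c + p].copy())
            need[label] -= take
    for label in (0, 1):
        if need[label] > 0:
            raise StarvedClassError(
                f"class {label}: {need[label]} of {config.n_train_patches_per_class} "
                f"patches could not be sampled from the manifest"
            )
    patches = np.stack(got[0] + got[1])
    labels = np.array([0] * len(got[0]) + [1] * len(got[1]))
    train_set = LabeledPatchSet(patches, labels, purity=config.train_purity)
    clf = fit_classifier(train_set, reg_strength=config.reg_strength, seed=config.seed)
    config.classifier_path.parent.mkdir(parents=True, exist_ok=True)
    clf.save(config.classifier_path)
    log.info(
        "train: config %s, %d patches/class, training accuracy %.4f -> %s",
        config.config_hash(),
        config.n_train_patches_per_class,
        clf.train_accuracy,
        config.classifier_path,
    )
    return clf


def run_quantify(config: RunConfig, save_images: bool = True) -> pd.DataFrame:
    """Quantify every manifest slide; one CSV row per slide.

    A slide with no detectable tissue is kept in the table with an empty
    ratio and a ``no tissue`` note, never as a 0/0.
    """
    manifest, base = _load_manifest(config)
    clf = PatchClassifier.load(config.classifier_path)
    maps_dir = config.outdir / "maps"
    if save_images:
        maps_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for _, mrow in manifest.iterrows():
        slide_id = str(mrow.get("animal_id", mrow["image_path"]))
        image = np.asarray(iio.imread(base / mrow["image_path"]))
        row: dict[str, Any] = {
            "slide_id": slide_id,
            "arm": mrow.get("arm", ""),
            "a_tissue_px": 0,
            "a_lesion_px": 0,
            "ratio": np.nan,
            "n_components": 0,
            "theta": config.theta,
            "patch_size": config.patch_size,
            "stride": config.stride,
            "note": "",
        }
        if "planted_fraction" in manifest.columns:
            row["planted_fraction"] = mrow["planted_fraction"]
        try:
            out = quantify_slide(
                image,
                clf,
                slide_id=slide_id,
                stride=config.stride,
                min_tissue_frac=config.min_tissue_frac,
                theta=config.theta,
                morphology=config.morphology,
                min_component_area_px=config.min_component_area_px,
            )
        except NoTissueError:
            row["note"] = "no tissue"
            rows.append(row)
            continue
        row.update(
            a_tissue_px=out.result.a_tissue_px,
            a_lesion_px=out.result.a_lesion_px,
            ratio=out.result.ratio,
            n_components=out.result.n_lesion_components,
        )
        rows.append(row)
        if save_images:
            iio.imwrite(
                maps_dir / f"{slide_id}_likelihood.png",
                np.rint(out.likelihood.values * 65535).astype(np.uint16),
            )
            iio.imwrite(
                maps_dir / f"{slide_id}_lesion.png",
                out.lesion.mask.astype(np.uint8) * 255,
            )
    results = pd.DataFrame(rows)
    config.results_path.parent.mkdir(parents=True, exist_ok=True)
    results.to_csv(config.results_path, index=False)
    log.info("quantify: config %s, %d slides -> %s", config.config_hash(), len(results), config.results_path)
    return results


def compare_arms(
    results: pd.DataFrame,
    provenance: dict[str, Any] | None = None,
) -> ExperimentReport:
    """Arm summaries and contrasts from a per-slide results table.

    A slide counts as affected when at least one lesion component survived
    the minimum-area filter.  Two arms get a pooled t-test on the burden
    ratio plus chi-square and Fisher tests on the affected counts; three or
    more arms additionally get one-way ANOVA with Bonferroni post hoc.
    """
    if "arm" not in results.columns:
        raise ValueError("results table lacks an 'arm' column")
    usable = results.dropna(subset=["ratio"])
    arm_names = [str(a) for a in pd.unique(usable["arm"])]
    if len(arm_names) < 2:
        raise ValueError("need at least two arms to compare")
    groups: dict[str, pd.DataFrame] = {a: usable[usable["arm"] == a] for a in arm_names}
    summaries: dict[str, stats.GroupSummary] = {}
    arm_rows = []
    for a in arm_names:
        g = groups[a]
        s = stats.summarize_arm(a, g["ratio"].tolist())
        k = int((g["n_components"] >= 1).sum())
        s = stats.GroupSummary(a, s.n, k, s.mean, s.sd)
        summaries[a] = s
        arm_rows.append(
            {
                "arm": a,
                "n": s.n,
                "k_affected": s.k_affected,
                "incidence_pct": s.incidence_pct,
                "mean_ratio": s.mean,
                "sd_ratio": s.sd,
            }
        )
    contrast_rows = []

    def add(contrast: str, res: stats.TestResult) -> None:
        df = res.df
        contrast_rows.append(
            {
                "contrast": contrast,
                "test": res.test_name,
                "statistic": res.statistic,
                "df": str(df),
                "p_value": res.p_value,
                "note": res.note,
            }
        )

    for i in range(len(arm_names)):
        for j in range(i + 1, len(arm_names)):
            a, b = arm_names[i], arm_names[j]
            sa, sb = summaries[a], summaries[b]
            label = f"{a} vs {b}"
            add(label, stats.pooled_t_test(sa.mean, sa.sd, sa.n, sb.mean, sb.sd, sb.n))
            table = (sa.k_affected, sa.n - sa.k_affected, sb.k_affected, sb.n - sb.k_affected)
            try:
                add(label, stats.chi_square_2x2(*table))
                add(label, stats.fisher_exact_2x2(*table))
            except ValueError as e:  # zero margin: all or none affected in both arms
                contrast_rows.append(
                    {
                        "contrast": label,
                        "test": "chi-square/fisher",
                        "statistic": np.nan,
                        "df": "",
                        "p_value": np.nan,
                        "note": f"skipped: {e}",
                    }
                )
    if len(arm_names) >= 3:
        value_groups = [groups[a]["ratio"].tolist() for a in arm_names]
        add(" vs ".join(arm_names), stats.one_way_anova(value_groups))
        for a, b, res in stats.posthoc_pairwise(value_groups, arm_names):
            add(f"{a} vs {b} (post hoc)", res)
    return ExperimentReport(
        per_slide=results,
        arms=pd.DataFrame(arm_rows),
        contrasts=pd.DataFrame(contrast_rows),
        provenance=provenance or {},
    )


def run_compare(config: RunConfig) -> ExperimentReport:
    """Compare arms from the per-slide results CSV; writes CSVs + summary."""
    if not Path(config.results_path).exists():
        raise FileNotFoundError(f"results not found: {config.results_path}")
    results = pd.read_csv(config.results_path)
    from . import __version__

    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "lesionquant_version": __version__,
    }
    report = compare_arms(results, provenance)
    config.outdir.mkdir(parents=True, exist_ok=True)
    report.arms.to_csv(config.outdir / "arms.csv", index=False)
    report.contrasts.to_csv(config.outdir / "contrasts.csv", index=False)
    lines = [f"# lesionquant arm comparison (config {provenance['config_hash']}, seed {config.seed})", ""]
    for _, r in report.arms.iterrows():
        lines.append(
            f"{r['arm']}: n={r['n']}, affected {r['k_affected']}/{r['n']} "
            f"({r['incidence_pct']:.1f}%), ratio {100 * r['mean_ratio']:.2f}% "
            f"± {100 * r['sd_ratio']:.2f}%"
        )
    lines.append("")
    for _, r in report.contrasts.iterrows():
        lines.append(
            f"{r['contrast']} [{r['test']}]: statistic={r['statistic']:.4g}, "
            f"df={r['df']}, p={r['p_value']:.4g} {r['note']}"
        )
    (config.outdir / "summary.txt").write_text("\n".join(lines) + "\n")
    log.info("compare: config %s -> %s", config.config_hash(), config.outdir / "summary.txt")
    return report


def incidence_table(counts: Sequence[tuple[str, int, int]]) -> pd.DataFrame:
    """Incidence percentages from printed (arm, k_affected, n) counts."""
    rows = [
        {"arm": arm, "k_affected": k, "n": n, "incidence_pct": stats.incidence_percent(k, n)}
        for arm, k, n in counts
    ]
    return pd.DataFrame(rows)


def run_report(config: RunConfig) -> Path:
    """Bundle the comparison into report.json plus a per-arm scatter figure."""
    report = run_compare(config)
    doc = {
        "provenance": report.provenance,
        "arms": report.arms.to_dict(orient="records"),
        "contrasts": report.contrasts.to_dict(orient="records"),
        "n_slides": int(len(report.per_slide)),
    }
    out = config.outdir / "report.json"
    out.write_text(json.dumps(doc, indent=1, default=float))
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 3))
        usable = report.per_slide.dropna(subset=["ratio"])
        arms = list(pd.unique(usable["arm"]))
        rng = np.random.default_rng(0)
        for i, a in enumerate(arms):
            y = usable.loc[usable["arm"] == a, "ratio"].to_numpy() * 100
            x = i + rng.uniform(-0.08, 0.08, size=y.size)
            ax.plot(x, y, "o", alpha=0.7, label=a)
        ax.set_xticks(range(len(arms)), arms)
        ax.set_ylabel("lesion burden A$_{lesion}$/A$_{tissue}$ (%)")
        fig.tight_layout()
        fig.savefig(config.outdir / "ratios.png", dpi=150)
        plt.close(fig)
    except Exception as e:  # plotting is best-effort; the tables are the product
        log.warning("report figure skipped: %s", e)
    log.info("report: config %s -> %s", config.config_hash(), out)
    return out
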