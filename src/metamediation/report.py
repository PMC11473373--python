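"""Pipeline orchestration and report rendering.

``run_full_analysis`` stitches the stages together for each polarity
stratum: per-relation random-effects pooling, publication-bias
diagnostics, pooled-matrix assembly, mediation fit, and path CIs.  The
result bundle is a plain nested dict (JSON-serializable); renderers write
TSV tables mirroring the conventional meta-analysis report layout plus
funnel-plot data exports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .bias import fail_safe_n, funnel_data, trim_and_fill
from .coding import CodingTable, Polarity, read_coding_table, subset_by_polarity
from .effects import effects_from_table
from .masem import CELL_RELATIONS, CELLS, fit_mediation, mediation_ci, pool_matrix
from .meta import pool_random

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_full_analysis", "render_tables", "write_bundle"]

#: Human-readable relation labels, keyed by matrix cell.
RELATION_LABELS = {"xm": "PA-Re", "xy": "PA-MH", "my": "Re-MH"}


@dataclass
class RunConfig:
    """Everything one full analysis run needs, recorded for audit."""

    input_path: str | Path
    strata: list[Polarity] = field(
        default_factory=lambda: [Polarity.POSITIVE, Polarity.NEGATIVE]
    )
    alpha: float = 0.05
    tau2_estimator: str = "dl"
    ci_method: str = "monte_carlo"
    mc_reps: int = 100_000
    seed: int | None = None
    exclude_ids: list[str] = field(default_factory=list)
    output_dir: str | Path = "results"

    def __post_init__(self) -> None:
        self.strata = [Polarity.coerce(s) for s in self.strata]
        if self.ci_method == "monte_carlo" and self.seed is None:
            raise ValueError("a seed is mandatory when ci_method='monte_carlo'")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["input_path"] = str(self.input_path)
        out["output_dir"] = str(self.output_dir)
        out["strata"] = [s.value for s in self.strata]
        return out


def _stage(stratum: Polarity, stage: str):
    """Context text for error surfacing."""
    return f"[stratum={stratum.value}, stage={stage}]"


def run_full_analysis(config: RunConfig, table: CodingTable | None = None) -> dict:
    """Execute the complete pipeline and return the result bundle.

    ``table`` may be passed directly (e.g., a simulated one); otherwise it
    is read from ``config.input_path``.  Errors are re-raised with the
    stratum and stage prepended.
    """
    if table is None:
        table = read_coding_table(config.input_path, strict=True)
    logger.info(
        "run: k=%d studies, tau2=%s, ci=%s, seed=%s",
        table.k, config.tau2_estimator, config.ci_method, config.seed,
    )
    bundle: dict = {"config": config.to_dict(), "n_unique_subjects": table.unique_subjects,
                    "strata": {}}
    for stratum in config.strata:
        block: dict = {}
        sub = subset_by_polarity(table, stratum)
        if config.exclude_ids:
            known = set(sub.study_ids)
            sub = sub.exclude([s for s in config.exclude_ids if s in known])
        if sub.k == 0:
            raise ValueError(f"{_stage(stratum, 'subset')} no studies in stratum")
        block["k"] = sub.k

        pooled_by_cell = {}
        for cell in CELLS:
            relation = CELL_RELATIONS[cell]
            try:
                eff = effects_from_table(sub, relation)
                pooled = pool_random(eff, alpha=config.alpha,
                                     tau2_estimator=config.tau2_estimator)
                pooled_by_cell[cell] = (eff, pooled)
            except Exception as exc:
                raise type(exc)(f"{_stage(stratum, f'pool:{relation}')} {exc}") from exc
        block["pooled"] = {
            RELATION_LABELS[cell]: pooled.to_dict()
            for cell, (_, pooled) in pooled_by_cell.items()
        }

        block["bias"] = {}
        block["funnel"] = {}
        for cell, (eff, pooled) in pooled_by_cell.items():
            label = RELATION_LABELS[cell]
            try:
                fsn = fail_safe_n(eff, alpha=config.alpha)
                tf = trim_and_fill(eff, side="auto", alpha=config.alpha,
                                   tau2_estimator=config.tau2_estimator)
                block["bias"][label] = {
                    "fail_safe_n": fsn.n_fs,
                    "fail_safe_threshold": fsn.threshold,
                    "fail_safe_exceeds": fsn.exceeds_threshold,
                    "trim_fill_k0": tf.k0,
                    "trim_fill_side": tf.side,
                    "trim_fill_adjusted_r": tf.adjusted.r_pooled,
                }
                block["funnel"][label] = funnel_data(eff, pooled, alpha=config.alpha)
            except Exception as exc:
                raise type(exc)(f"{_stage(stratum, f'bias:{label}')} {exc}") from exc

        try:
            matrix = pool_matrix(sub, stratum, alpha=config.alpha,
                                 tau2_estimator=config.tau2_estimator)
            block["matrix"] = matrix.to_dict()
        except Exception as exc:
            raise type(exc)(f"{_stage(stratum, 'pool_matrix')} {exc}") from exc

        try:
            fit = fit_mediation(matrix)
            cis = mediation_ci(
                matrix, method=config.ci_method, reps=config.mc_reps,
                seed=config.seed, alpha=config.alpha,
            )
            fit = dataclasses.replace(
                fit, ci_a=cis["a"], ci_b=cis["b"], ci_c=cis["c"], ci_ab=cis["ab"]
            )
            block["mediation"] = fit.to_dict()
            block["path_model"] = fit.path_model_text()
        except Exception as exc:
            raise type(exc)(f"{_stage(stratum, 'mediation')} {exc}") from exc

        bundle["strata"][stratum.value] = block
    return bundle


def _fmt(x, nd=3) -> str:
    return f"{x:.{nd}f}"


def render_tables(bundle: dict, output_dir) -> list[Path]:
    """Write the TSV report files and results.json; returns written paths.

    Layouts: ``table2.tsv`` pooled effects with heterogeneity and bias
    diagnostics per stratum-relation; ``table3.tsv`` the pooled matrices;
    ``table4.tsv`` the mediation paths; ``funnel_<stratum>.tsv`` per-study
    funnel coordinates.  Rendering is deterministic: identical bundles
    give identical bytes.
    """
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    lines = ["stratum\trelation\tk\tr\tci_low\tci_high\tz\tp\tQ\tdf\tp_Q\tI2\tfail_safe_N\ttrim_fill_k0\tadjusted_r"]
    for stratum, block in bundle["strata"].items():
        for label, pooled in block["pooled"].items():
            bias = block["bias"][label]
            adj = (
                _fmt(bias["trim_fill_adjusted_r"])
                if bias["trim_fill_k0"] > 0
                else ""
            )
            flag = " (adjusted)" if bias["trim_fill_k0"] > 0 else ""
            lines.append(
                "\t".join(
                    [
                        stratum, label + flag, str(pooled["k"]),
                        _fmt(pooled["r"]), _fmt(pooled["ci_low"]), _fmt(pooled["ci_high"]),
                        _fmt(pooled["z"]), _fmt(pooled["p"]),
                        _fmt(pooled["Q"]), str(pooled["df"]), _fmt(pooled["p_Q"]),
                        _fmt(pooled["I2"], 2), str(bias["fail_safe_n"]),
                        str(bias["trim_fill_k0"]), adj,
                    ]
                )
            )
    path = outdir / "table2.tsv"
    path.write_text("\n".join(lines) + "\n")
    written.append(path)

    lines = ["stratum\tr_xm\tr_xy\tr_my\tn_harmonic\tk"]
    for stratum, block in bundle["strata"].items():
        m = block["matrix"]
        lines.append(
            "\t".join(
                [stratum, _fmt(m["r_xm"]), _fmt(m["r_xy"]), _fmt(m["r_my"]),
                 _fmt(m["n_harmonic"], 1), str(m["k"])]
            )
        )
    path = outdir / "table3.tsv"
    path.write_text("\n".join(lines) + "\n")
    written.append(path)

    lines = ["stratum\tk\ta\tci_a\tb\tci_b\tab\tci_ab\tc\tci_c\td\tproportion_mediated"]
    for stratum, block in bundle["strata"].items():
        med = block["mediation"]

        def ci(name):
            pair = med[name]
            return f"{_fmt(pair[0])}, {_fmt(pair[1])}" if pair else ""

        lines.append(
            "\t".join(
                [stratum, str(med["k"]), _fmt(med["a"]), ci("ci_a"),
                 _fmt(med["b"]), ci("ci_b"), _fmt(med["ab"]), ci("ci_ab"),
                 _fmt(med["c"]), ci("ci_c"), _fmt(med["d"]),
                 _fmt(med["proportion_mediated"], 2)]
            )
        )
    path = outdir / "table4.tsv"
    path.write_text("\n".join(lines) + "\n")
    written.append(path)

    for stratum, block in bundle["strata"].items():
        rows = ["relation\tstudy_id\tz\tse"]
        for label, funnel in block["funnel"].items():
            for _, point in funnel.points.iterrows():
                rows.append(
                    f"{label}\t{point['study_id']}\t{point['z']:.6f}\t{point['se']:.6f}"
                )
        path = outdir / f"funnel_{stratum}.tsv"
        path.write_text("\n".join(rows) + "\n")
        written.append(path)

    written.append(write_bundle(bundle, outdir / "results.json"))
    return written


def write_bundle(bundle: dict, path) -> Path:
    """Serialize the bundle to JSON (funnel frames reduced to records)."""
    path = Path(path)

    def default(obj):
        from .bias import FunnelData

        if isinstance(obj, FunnelData):
            return {
                "center": obj.center,
                "points": obj.points.to_dict(orient="records"),
            }
        raise TypeError(f"not JSON-serializable: {type(obj)}")

    path.write_text(json.dumps(bundle, indent=2, sort_keys=True, default=default) + "\n")
    return path
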