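"""Packaged fixtures, "mean ± sd" parsing, study configuration, and the
end-to-end analysis driver.

The published design/response/group tables ship as UTF-8 CSV inside the
package (``extractopt/data``), with cells kept verbatim in the paper's
"mean ± sd letter" notation.  A dedicated parser splits those cells into
numeric mean, SD, and significance letters; analysis code never touches the
raw strings.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import anova as anova_mod
from . import design as design_mod
from . import groupstats, hsi, optimize as optimize_mod, simulate as simulate_mod
from .exceptions import FixtureNotFoundError, ValidationError
from .rsm import ResponseTable, fit_quadratic, uncoded_equation

__all__ = [
    "parse_value_cell",
    "fixture_path",
    "fixture_names",
    "load_fixture",
    "load_bbd_design",
    "load_bbd_responses",
    "load_group_means",
    "StudyConfig",
    "run_full_analysis",
]

logger = logging.getLogger("extractopt")

SAMPLES = ("C1", "C2", "C3", "C4")
RESPONSES = ("TPC", "AA")

_FIXTURES = {
    "bbd_design": "bbd_design.csv",
    "tpc_bbd": "tpc_bbd.csv",
    "aa_bbd": "aa_bbd.csv",
    "optima": "optima.csv",
    "anova_tpc": "anova_tpc.csv",
    "anova_aa": "anova_aa.csv",
    "proximate": "proximate.csv",
    "extraction_comparison": "extraction_comparison.csv",
    "bread_color": "bread_color.csv",
    "bread_tpc_aa": "bread_tpc_aa.csv",
}

_CELL_RE = re.compile(
    r"^\s*(?P<mean>[+-]?\d+(?:\.\d+)?)"
    r"(?:\s*±\s*(?P<sd>\d+(?:\.\d+)?))?"
    r"(?:\s+(?P<letters>[a-z]+))?\s*$"
)


def parse_value_cell(cell: str):
    """Parse a ``"326 ± 2 a"`` style cell into (mean, sd, letters).

    SD and letters are optional; missing parts come back as None.
    """
    match = _CELL_RE.match(str(cell))
    if match is None:
        raise ValidationError(f"cannot parse value cell {cell!r}")
    mean = float(match.group("mean"))
    sd = match.group("sd")
    return mean, (None if sd is None else float(sd)), match.group("letters")


def fixture_names() -> list[str]:
    return sorted(_FIXTURES)


def fixture_path(name: str) -> Path:
    if name not in _FIXTURES:
        raise FixtureNotFoundError(
            f"unknown fixture {name!r}; available: {fixture_names()}"
        )
    return Path(resources.files("extractopt.data") / _FIXTURES[name])


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged fixture as a string-typed DataFrame.

    Cells are kept verbatim (digit-for-digit with the published tables);
    use :func:`parse_value_cell` or the typed loaders below for numbers.
    """
    path = fixture_path(name)
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def serialize_fixture(frame: pd.DataFrame) -> str:
    """Inverse of :func:`load_fixture`: CSV text, byte-identical round trip."""
    return frame.to_csv(index=False)


def load_bbd_design() -> design_mod.Design:
    """The study's Box-Behnken design (generated, not read from disk)."""
    return design_mod.build_box_behnken(design_mod.default_factors(), n_center=3)


def load_bbd_responses(response: str, sample: str) -> tuple[ResponseTable, np.ndarray]:
    """Experimental mean +/- SD table and the published predicted column.

    ``response`` is ``"TPC"`` or ``"AA"``; ``sample`` is ``"C1"``..``"C4"``.
    Replicate counts are 3 throughout (triplicated runs).
    """
    response = response.upper()
    if response not in RESPONSES:
        raise ValidationError(f"response must be one of {RESPONSES}, got {response!r}")
    if sample not in SAMPLES:
        raise ValidationError(f"sample must be one of {SAMPLES}, got {sample!r}")
    frame = load_fixture("tpc_bbd" if response == "TPC" else "aa_bbd")
    parsed = [parse_value_cell(c) for c in frame[f"{sample}_exp"]]
    table = ResponseTable.from_means(
        run_ids=frame["run"].astype(int),
        means=[p[0] for p in parsed],
        sds=[p[1] for p in parsed],
        n_reps=[3] * len(parsed),
        response_name=f"{response}_{sample}",
    )
    predicted = frame[f"{sample}_pred"].astype(float).to_numpy()
    return table, predicted


def load_group_means(name: str) -> pd.DataFrame:
    """Group-table fixture parsed to numbers: MultiIndex columns
    (variable, {mean, sd, letters}); index = the label column(s)."""
    frame = load_fixture(name)
    label_cols = [c for c in frame.columns if c in ("sample", "bread", "method")]
    value_cols = [c for c in frame.columns if c not in label_cols]
    out = {}
    for col in value_cols:
        parsed = [parse_value_cell(c) for c in frame[col]]
        out[(col, "mean")] = [p[0] for p in parsed]
        out[(col, "sd")] = [p[1] for p in parsed]
        out[(col, "letters")] = [p[2] for p in parsed]
    result = pd.DataFrame(out)
    result.index = pd.MultiIndex.from_frame(frame[label_cols]) if len(label_cols) > 1 \
        else pd.Index(frame[label_cols[0]], name=label_cols[0])
    return result


@dataclass
class StudyConfig:
    """Everything the end-to-end analysis needs, serializable to YAML/JSON."""

    factors: list[dict] = field(
        default_factory=lambda: [
            dataclasses.asdict(f) for f in design_mod.default_factors()
        ]
    )
    samples: tuple[str, ...] = SAMPLES
    responses: tuple[str, ...] = RESPONSES
    grid_steps: tuple[float, float, float] = optimize_mod.DEFAULT_GRID_STEPS
    sg_window: int = 7
    sg_polyorder: int = 2
    alpha: float = 0.05
    adjust: str = "bonferroni"
    mold_fraction: dict = field(
        default_factory=lambda: {"T1": 0.0, "T2": 0.0, "T3": 0.0, "T4": 0.10}
    )
    cube_shape: tuple[int, int] = (64, 64)
    cube_noise_sd: float = 0.025
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")

    def factor_specs(self) -> tuple[design_mod.FactorSpec, ...]:
        return tuple(design_mod.FactorSpec(**f) for f in self.factors)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["samples"] = list(self.samples)
        d["responses"] = list(self.responses)
        d["grid_steps"] = list(self.grid_steps)
        d["cube_shape"] = list(self.cube_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        for key in ("samples", "responses", "grid_steps", "cube_shape"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text(encoding="utf-8")))


def _fit_branch(config: StudyConfig, sample: str, response: str) -> dict:
    design = design_mod.build_box_behnken(config.factor_specs(), n_center=3)
    responses, predicted = load_bbd_responses(response, sample)
    fit = fit_quadratic(design, responses)
    table = anova_mod.anova_decomposition(fit)
    optimum = optimize_mod.optimize_response(fit.model, grid_steps=config.grid_steps)
    coefs, equation = uncoded_equation(fit.model)
    surfaces = {}
    for pair in (("X1", "X2"), ("X1", "X3"), ("X2", "X3")):
        held = ({"X1", "X2", "X3"} - set(pair)).pop()
        idx = int(held[1]) - 1
        grid = optimize_mod.surface_grid(
            fit.model, pair, fixed_value=design.factors[idx].center
        )
        surfaces["x".join(pair)] = grid
    return {
        "fit": fit,
        "coef_uncoded": coefs,
        "equation": equation,
        "anova": table,
        "optimum": optimum,
        "surfaces": surfaces,
        "published_predicted": predicted,
    }


def run_full_analysis(config: StudyConfig | None = None, out_dir=None) -> dict:
    """Run every stage on the packaged fixtures plus a simulated shelf series.

    Produces, per sample x response: the fitted model (coded and uncoded),
    ANOVA table, optimum, and three surface grids; plus mean derivative
    spectra and PCA scores for a simulated storage series; plus the bread
    enrichment percent changes.  Returns a report dict; with ``out_dir``,
    the machine-readable artifacts are also written to disk.
    """
    config = config or StudyConfig()
    report: dict = {"config": config.to_dict(), "models": {}}

    for sample in config.samples:
        for response in config.responses:
            logger.info("fitting %s %s", sample, response)
            branch = _fit_branch(config, sample, response)
            fit = branch["fit"]
            table = branch["anova"]
            opt = branch["optimum"]
            report["models"][f"{sample}_{response}"] = {
                "coef_coded": fit.model.coef.tolist(),
                "coef_uncoded": fit.model.to_uncoded().coef.tolist(),
                "equation": branch["equation"],
                "r2": table.r2,
                "r2_adj": table.r2_adj,
                "optimum": {
                    "settings": list(opt.settings),
                    "predicted": opt.predicted,
                    "desirability": opt.desirability,
                },
                "fitted": fit.fitted.tolist(),
            }

    # Shelf-life monitoring on a simulated storage series.
    logger.info("simulating shelf-life series (seed=%d)", config.seed)
    cube_spec = simulate_mod.CubeSpec(
        shape=config.cube_shape,
        mold_fraction=config.mold_fraction,
        noise_sd=config.cube_noise_sd,
        seed=config.seed,
    )
    frames = simulate_mod.simulate_shelf_cubes(cube_spec)
    spectra = {}
    for frame in frames:
        corrected = hsi.correct_reflectance(frame.cube)
        mask = hsi.segment_foreground(corrected)
        spectra[frame.time] = hsi.mean_spectrum(corrected, mask)
    sset = hsi.SpectrumSet(wavelengths=frames[0].cube.wavelengths, spectra=spectra)
    deriv = hsi.sg_first_derivative(sset, config.sg_window, config.sg_polyorder)
    pca = hsi.pca_spectra(deriv, n_components=2)
    keys, _ = deriv.matrix()
    report["shelf_life"] = {
        "times": keys,
        "scores": pca.scores.tolist(),
        "explained_variance_pct": pca.explained_variance_pct.tolist(),
        "mold_fraction": config.mold_fraction,
    }

    # Bread enrichment percent changes relative to the control loaf.
    bread = load_group_means("bread_tpc_aa")
    changes = {}
    for variable in ("TPC", "AA"):
        ref = float(bread.loc["P1", (variable, "mean")])
        for treated in ("P2", "P3"):
            val = float(bread.loc[treated, (variable, "mean")])
            changes[f"{treated}_{variable}"] = groupstats.percent_change_rendered(ref, val)
    report["bread_percent_change"] = changes

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(
            json.dumps(report, indent=2), encoding="utf-8"
        )
    return report
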