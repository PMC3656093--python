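"""Synthetic duplicate-screen generator with known ground truth.

Emulates a pilot single-point screen of ~2,000 compounds on 384-well plates:
each plate carries a column of neutral (vehicle) control wells and a column of
positive (full-inhibition) control wells; compounds fill the remaining wells
sequentially, with the identical compound-to-well assignment in every
replicate.  The raw signal of a well is

    raw = neutral_mean * (1 - effect) * (1 + positional_bias) * noise

where ``effect`` is the fraction of reporter signal suppressed (0 for neutral
controls, ``positive_effect`` for positive controls, the compound's true
effect otherwise), ``positional_bias`` is an additive separable row+column
gradient shared by all plates (an instrument artifact the pattern correction
is meant to remove), and ``noise`` is a mean-1 multiplicative lognormal
(luminescence is positive and right-skewed; a Gaussian option exists for
calibration studies that assume symmetric noise).

Two noise scales are distinguished: ``neutral_cv`` is the well-to-well
variability of the control columns (edge wells, which in practice run noisier
than interior wells and set the assay's Z'-factor), while
``replicate_noise_cv`` is the run-to-run repeatability of a compound well
(which sets the replicate concordance).  Compound truth mixes a small
fraction of genuine inhibitors (uniform effects within
``inhibitor_effect_range``) with a mild Gaussian background of reproducible
low-level bioactivity (``background_effect_sd``) present in any real library.

Ground truth (true effects, inhibitor status, dose-response parameters,
promiscuity status) is serialized alongside the data and is never consumed by
the analysis stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace, asdict

import numpy as np
import pandas as pd
import yaml

from .dose_response import four_pl

__all__ = [
    "ScreenConfigError",
    "ScreenConfig",
    "DoseDesign",
    "generate_screen",
    "generate_null_screen",
    "generate_dose_series",
    "generate_annotations",
    "generate_promiscuity",
    "write_config",
    "read_config",
]


class ScreenConfigError(ValueError):
    """Invalid screen configuration (e.g. more wells requested than the plate holds)."""


@dataclass(frozen=True)
class ScreenConfig:
    """Study conditions for a synthetic duplicate screen.

    Defaults describe a 1,982-compound pilot screen in duplicate on 16x24
    plates at 9.4 uM, with one neutral and one positive control column per
    plate, and noise levels calibrated so that per-plate Z'-factors
    concentrate in the low 0.8s and replicate concordance (r^2) lands near
    0.9.
    """

    n_compounds: int = 1982
    n_replicates: int = 2
    n_rows: int = 16
    n_cols: int = 24
    n_neutral_wells_per_plate: int = 16
    n_positive_wells_per_plate: int = 16
    neutral_mean: float = 10000.0
    neutral_cv: float = 0.07
    positive_effect: float = 0.98
    frac_true_inhibitors: float = 0.04
    inhibitor_effect_range: tuple[float, float] = (0.30, 0.99)
    background_effect_sd: float = 0.06
    plate_gradient_amplitude: float = 0.02
    replicate_noise_cv: float = 0.015
    compound_concentration_uM: float = 9.4
    noise_model: str = "lognormal"
    seed: int = 0

    def __post_init__(self):
        for name in ("neutral_cv", "positive_effect", "frac_true_inhibitors",
                     "plate_gradient_amplitude", "replicate_noise_cv"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ScreenConfigError(f"{name}={v} outside [0, 1]")
        lo, hi = self.inhibitor_effect_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise ScreenConfigError(f"inhibitor_effect_range {lo, hi} invalid")
        for name in ("n_compounds", "n_replicates", "n_rows", "n_cols"):
            if getattr(self, name) <= 0:
                raise ScreenConfigError(f"{name} must be positive")
        if self.n_neutral_wells_per_plate < 2 or self.n_positive_wells_per_plate < 2:
            raise ScreenConfigError("need >=2 control wells of each kind per plate")
        if (self.n_neutral_wells_per_plate > self.n_rows
                or self.n_positive_wells_per_plate > self.n_rows):
            raise ScreenConfigError("control wells exceed one plate column")
        if self.compound_capacity_per_plate <= 0:
            raise ScreenConfigError("plate overflow: no room for compound wells")
        if self.noise_model not in ("lognormal", "normal"):
            raise ScreenConfigError(f"unknown noise_model {self.noise_model!r}")
        if self.neutral_mean <= 0:
            raise ScreenConfigError("neutral_mean must be positive")

    @property
    def compound_capacity_per_plate(self) -> int:
        # controls occupy the first and last columns
        return self.n_rows * (self.n_cols - 2)

    @property
    def n_plates(self) -> int:
        return math.ceil(self.n_compounds / self.compound_capacity_per_plate)


@dataclass(frozen=True)
class DoseDesign:
    """Dilution-series design: ``n_doses`` doses descending 2-fold from
    ``top_concentration`` (defaults: 50 uM down to 0.39 uM over 8 doses)."""

    top_concentration: float = 50.0
    dilution_factor: float = 2.0
    n_doses: int = 8
    replicates_per_dose: int = 2

    def __post_init__(self):
        if self.top_concentration <= 0:
            raise ValueError("top_concentration must be positive")
        if self.dilution_factor <= 1:
            raise ValueError("dilution_factor must exceed 1")
        if self.n_doses < 1 or self.replicates_per_dose < 1:
            raise ValueError("n_doses and replicates_per_dose must be >=1")

    @property
    def concentrations(self) -> np.ndarray:
        return self.top_concentration / self.dilution_factor ** np.arange(self.n_doses)


def _noise_factors(rng: np.random.Generator, cv: float, size: int, model: str) -> np.ndarray:
    if cv == 0.0:
        return np.ones(size)
    if model == "lognormal":
        sigma = math.sqrt(math.log1p(cv * cv))
        return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)
    return np.maximum(1.0 + rng.normal(0.0, cv, size=size), 0.0)


def _truth_table(cfg: ScreenConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_compounds
    ids = np.array([f"C{i + 1:05d}" for i in range(n)])
    is_inhib = rng.random(n) < cfg.frac_true_inhibitors
    lo, hi = cfg.inhibitor_effect_range
    effect = np.where(
        is_inhib,
        rng.uniform(lo, hi, size=n),
        rng.normal(0.0, cfg.background_effect_sd, size=n),
    )
    effect = np.clip(effect, -0.95, 0.999)
    # Dose-response truth for inhibitors (span as percent of control signal).
    ic50 = np.exp(rng.uniform(math.log(1.0), math.log(20.0), size=n))
    hill = rng.uniform(0.8, 2.5, size=n)
    return pd.DataFrame(
        {
            "compound_id": ids,
            "is_inhibitor": is_inhib,
            "true_effect": effect,
            "true_ic50_uM": np.where(is_inhib, ic50, np.nan),
            "true_hill": np.where(is_inhib, hill, np.nan),
            "true_span_pct": np.where(is_inhib, 100.0 * np.abs(effect), 0.0),
        }
    )


def _layout(cfg: ScreenConfig) -> tuple[np.ndarray, np.ndarray]:
    """Compound well coordinates in fill order: column-major over cols 1..n-2."""
    rows, cols = [], []
    for c in range(1, cfg.n_cols - 1):
        for r in range(cfg.n_rows):
            rows.append(r)
            cols.append(c)
    return np.array(rows), np.array(cols)


def generate_screen(config: ScreenConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate a complete duplicate screen.

    Returns ``(wells, library, truth)``: a well table covering every
    replicate (identical compound placement in each), the compound library
    table, and the ground-truth table.  Byte-identical for identical
    ``(config, seed)``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    truth = _truth_table(cfg, rng)

    cap = cfg.compound_capacity_per_plate
    n_plates = cfg.n_plates
    rows_fill, cols_fill = _layout(cfg)

    rowf = np.linspace(-0.5, 0.5, cfg.n_rows)
    colf = np.linspace(-0.5, 0.5, cfg.n_cols)

    comp_idx = np.arange(cfg.n_compounds)
    comp_plate = comp_idx // cap
    comp_slot = comp_idx % cap
    comp_row = rows_fill[comp_slot]
    comp_col = cols_fill[comp_slot]

    frames = []
    for rep in range(cfg.n_replicates):
        rep_id = f"r{rep + 1}"
        for p in range(n_plates):
            plate_id = f"P{p + 1:02d}"
            on_plate = comp_plate == p
            n_comp = int(on_plate.sum())
            r = comp_row[on_plate]
            c = comp_col[on_plate]
            eff = truth["true_effect"].to_numpy()[on_plate]
            bias = cfg.plate_gradient_amplitude * (rowf[r] + colf[c])
            base = cfg.neutral_mean * (1.0 - eff) * (1.0 + bias)
            sig = base * _noise_factors(rng, cfg.replicate_noise_cv, n_comp, cfg.noise_model)
            comp_df = pd.DataFrame(
                {
                    "plate_id": plate_id,
                    "row": r,
                    "col": c,
                    "well_type": "compound",
                    "compound_id": truth["compound_id"].to_numpy()[on_plate],
                    "concentration_uM": cfg.compound_concentration_uM,
                    "raw_signal": np.maximum(sig, 0.0),
                    "replicate_id": rep_id,
                }
            )
            # empty filler wells on a partially used plate
            n_empty = cap - n_comp
            empty_df = pd.DataFrame(
                {
                    "plate_id": plate_id,
                    "row": rows_fill[n_comp:cap],
                    "col": cols_fill[n_comp:cap],
                    "well_type": "empty",
                    "compound_id": None,
                    "concentration_uM": np.nan,
                    "raw_signal": 0.0,
                    "replicate_id": rep_id,
                }
            ) if n_empty else None

            ctrl_frames = []
            for wtype, col_idx, n_ctrl, eff_ctrl in (
                ("neutral", 0, cfg.n_neutral_wells_per_plate, 0.0),
                ("positive", cfg.n_cols - 1, cfg.n_positive_wells_per_plate,
                 cfg.positive_effect),
            ):
                rr = np.arange(n_ctrl)
                bias_c = cfg.plate_gradient_amplitude * (rowf[rr] + colf[col_idx])
                base_c = cfg.neutral_mean * (1.0 - eff_ctrl) * (1.0 + bias_c)
                sig_c = base_c * _noise_factors(rng, cfg.neutral_cv, n_ctrl, cfg.noise_model)
                ctrl_frames.append(
                    pd.DataFrame(
                        {
                            "plate_id": plate_id,
                            "row": rr,
                            "col": col_idx,
                            "well_type": wtype,
                            "compound_id": None,
                            "concentration_uM": np.nan,
                            "raw_signal": np.maximum(sig_c, 0.0),
                            "replicate_id": rep_id,
                        }
                    )
                )
            plate_frames = [f for f in (comp_df, empty_df, *ctrl_frames) if f is not None]
            frames.append(pd.concat(plate_frames, ignore_index=True))
    wells = pd.concat(frames, ignore_index=True)
    wells = wells.sort_values(
        ["replicate_id", "plate_id", "col", "row"], kind="mergesort"
    ).reset_index(drop=True)

    library = pd.DataFrame(
        {
            "compound_id": truth["compound_id"],
            "pubchem_cid": 100000 + np.arange(cfg.n_compounds),
            "screen_concentration_uM": cfg.compound_concentration_uM,
        }
    )
    return wells, library, truth


def generate_null_screen(n_compounds: int, config: ScreenConfig | None = None) -> pd.DataFrame:
    """A screen with no true bioactivity at all (pure noise), for calibration."""
    cfg = config or ScreenConfig()
    cfg = replace(
        cfg, n_compounds=n_compounds, frac_true_inhibitors=0.0, background_effect_sd=0.0
    )
    wells, _, _ = generate_screen(cfg)
    return wells


def generate_dose_series(
    L: float,
    h: float,
    alpha: float | None,
    beta: float,
    design: DoseDesign,
    noise_cv: float = 0.05,
    seed: int = 0,
    compound_id: str = "C00001",
    assay_context: str = "default",
) -> pd.DataFrame:
    """Simulate a dilution-series response from true 4PL parameters.

    ``alpha=None`` (or ``h=0``) produces a flat series at ``L``.  Responses
    are the noiseless curve times ``(1 + noise)`` with Gaussian noise of the
    given CV, so the expected response equals the noiseless curve.
    """
    rng = np.random.default_rng(seed)
    conc = design.concentrations
    x = np.repeat(conc, design.replicates_per_dose)
    if alpha is None or h == 0.0:
        y0 = np.full(x.size, float(L))
    else:
        if alpha <= 0:
            raise ValueError("alpha must be positive")
        y0 = four_pl(x, L, h, alpha, beta)
    noise = rng.normal(0.0, noise_cv, size=x.size) if noise_cv > 0 else np.zeros(x.size)
    return pd.DataFrame(
        {
            "compound_id": compound_id,
            "assay_context": assay_context,
            "concentration_uM": x,
            "response": y0 * (1.0 + noise),
            "viability": np.nan,
        }
    )


def generate_annotations(
    truth: pd.DataFrame,
    seed: int = 0,
    n_random_terms: int = 116,
    enriched_term: str = "reporter pathway inhibitor",
    enriched_size: int = 30,
    term_size_range: tuple[int, int] = (3, 40),
) -> pd.DataFrame:
    """Annotation term sets over the library: one genuinely inhibitor-enriched
    term plus random (null) terms, mirroring a pharmacological-action
    vocabulary of ~117 sets."""
    rng = np.random.default_rng(seed)
    ids = truth["compound_id"].to_numpy()
    inhib = truth.loc[truth["is_inhibitor"], "compound_id"].to_numpy()
    rows = []
    n_core = min(enriched_size, inhib.size)
    members = list(rng.choice(inhib, size=n_core, replace=False))
    members += list(rng.choice(ids, size=max(0, enriched_size - n_core), replace=False))
    for cid in dict.fromkeys(members):  # dedupe, keep order
        rows.append((enriched_term, cid))
    lo, hi = term_size_range
    for t in range(n_random_terms):
        size = int(rng.integers(lo, hi + 1))
        for cid in rng.choice(ids, size=size, replace=False):
            rows.append((f"term_{t + 1:03d}", cid))
    return pd.DataFrame(rows, columns=["term", "compound_id"])


def generate_promiscuity(
    truth: pd.DataFrame, seed: int = 0, frac_promiscuous: float = 0.02
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assay-history records; a chosen fraction are genuine frequent hitters.

    Returns ``(records, truth_with_flag)``; the flag column records which
    compounds were generated as promiscuous.
    """
    rng = np.random.default_rng(seed)
    n = len(truth)
    promiscuous = rng.random(n) < frac_promiscuous
    tested = np.where(
        promiscuous, rng.integers(60, 400, size=n), rng.integers(1, 120, size=n)
    )
    base_hits = rng.binomial(tested, 0.05)
    promiscuous_hits = np.ceil(tested * rng.uniform(0.30, 0.60, size=n)).astype(int)
    hits = np.where(promiscuous, promiscuous_hits, base_hits)
    # keep non-promiscuous records below the frequent-hitter rule
    cap = np.floor(tested * 0.25).astype(int)
    hits = np.where(~promiscuous & (tested > 50), np.minimum(hits, cap), hits)
    hits = np.minimum(hits, tested)
    records = pd.DataFrame(
        {
            "compound_id": truth["compound_id"],
            "n_assays_tested": tested,
            "n_assays_hit": hits,
        }
    )
    truth_flagged = truth.copy()
    truth_flagged["is_promiscuous"] = promiscuous
    return records, truth_flagged


def write_config(cfg: ScreenConfig, path) -> None:
    d = asdict(cfg)
    d["inhibitor_effect_range"] = list(d["inhibitor_effect_range"])
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def read_config(path) -> ScreenConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if "inhibitor_effect_range" in d:
        d["inhibitor_effect_range"] = tuple(d["inhibitor_effect_range"])
    return ScreenConfig(**d)
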