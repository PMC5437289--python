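"""Synthetic ¹³C tracing studies with known ground truth.

Real GC-MS tracing data are measured areas per isotopologue that mix the
tracer signal with natural isotope abundance, tracer impurity and detector
noise.  This module generates every input the pipeline consumes from a
planted labeling state, so recovery can be scored exactly:

* a true MID per metabolite × condition (binomial-mixture or two-pool
  labeling; in both, total carbon contribution equals the labeled-molecule
  fraction f exactly);
* raw areas obtained by forward-convolving the true MID with the fragment's
  natural-abundance/purity correction matrix and applying multiplicative
  log-normal noise (the standard model of MS intensity noise) — optionally
  rendered as Gaussian-peak ion chromatograms;
* sample sheets, media fresh/spent concentration tables and qPCR Ct tables
  with stated effect sizes.

The default study emulates a 2D-vs-3D growth contrast: a proline-like
metabolite with lower 3D carbon contribution and lower 3D level, net
proline secretion in 2D turning into uptake in 3D, a PRODH-like transcript
about 4-fold up in 3D, and several unaffected metabolites serving as
planted nulls.  All randomness flows from a single seed fanned out
deterministically per output section, so partial regeneration is stable.
"""

from __future__ import annotations

import dataclasses
import hashlib
from collections.abc import Mapping
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats

from .chem_core import FragmentSpec, IsotopeTable, example_fragment_library
from .isotope_correction import TracerPurity, build_correction_matrix
from .peak_integration import RawMID

__all__ = [
    "MetaboliteSpec",
    "NoiseModel",
    "StudyBundle",
    "StudyDesign",
    "default_study",
    "forward_measure",
    "simulate_level_table",
    "simulate_mid",
    "simulate_study",
    "write_chromatograms",
]


@dataclasses.dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise settings: multiplicative log-normal σ on ion areas,
    additive baseline-drift amplitude for chromatogram rendering, and the
    master seed (identical seed ⇒ identical dataset)."""

    sigma: float = 0.01
    baseline_drift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0 or self.baseline_drift < 0:
            raise ValueError("noise parameters must be >= 0")


@dataclasses.dataclass(frozen=True)
class MetaboliteSpec:
    """Planted ground truth for one metabolite across conditions."""

    name: str
    labeled_fraction: Mapping[str, float]  # condition -> f
    level: Mapping[str, float]             # condition -> true normalized level
    labeling_model: str = "binomial-mixture"


@dataclasses.dataclass(frozen=True)
class StudyDesign:
    """Conditions, replicate counts, tracer and planted effect sizes."""

    conditions: tuple[str, ...] = ("2D", "3D")
    control: str = "2D"
    n_replicates: int = 3
    tracer: str = "13C6-glucose"
    purity: float | None = 0.99
    metabolites: tuple[MetaboliteSpec, ...] = ()
    # gene -> condition -> true ΔCt (Ct_target − Ct_reference)
    gene_dct: Mapping[str, Mapping[str, float]] = dataclasses.field(default_factory=dict)
    # metabolite -> condition -> (fresh µM, spent µM) media concentrations
    media: Mapping[str, Mapping[str, tuple[float, float]]] = dataclasses.field(default_factory=dict)
    media_volume_ml: float = 2.0
    media_span_h: float = 72.0
    biomass_mg: float = 1.0
    biomass_kind: str = "protein"

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError(
                "tested contrasts need >= 2 replicates per condition "
                f"(got {self.n_replicates})"
            )
        if self.control not in self.conditions:
            raise ValueError(f"control {self.control!r} not among conditions")
        for spec in self.metabolites:
            for mapping in (spec.labeled_fraction, spec.level):
                missing = set(self.conditions) - set(mapping)
                if missing:
                    raise ValueError(f"{spec.name}: missing conditions {sorted(missing)}")


def default_study() -> StudyDesign:
    """The default 2D-vs-3D study: proline effect planted among nulls."""
    return StudyDesign(
        metabolites=(
            # proline-like effect: contribution and level both halved in 3D
            MetaboliteSpec("proline", {"2D": 0.40, "3D": 0.20}, {"2D": 1.0, "3D": 0.5}),
            MetaboliteSpec("alanine", {"2D": 0.60, "3D": 0.60}, {"2D": 1.0, "3D": 1.0}),
            MetaboliteSpec("glutamate", {"2D": 0.50, "3D": 0.50}, {"2D": 2.0, "3D": 2.0}),
            MetaboliteSpec("citrate", {"2D": 0.45, "3D": 0.45}, {"2D": 1.5, "3D": 1.5}),
            MetaboliteSpec("serine", {"2D": 0.30, "3D": 0.30}, {"2D": 0.8, "3D": 0.8}),
            MetaboliteSpec("lactate", {"2D": 0.70, "3D": 0.70}, {"2D": 3.0, "3D": 3.0}),
        ),
        gene_dct={
            # PRODH-like: ΔCt two cycles lower in 3D → 4-fold up
            "PRODH": {"2D": 6.0, "3D": 4.0},
            "PYCR1": {"2D": 5.0, "3D": 5.0},
            "P5CS": {"2D": 7.0, "3D": 7.0},
        },
        media={
            # secretion (negative rate) in 2D, net uptake in 3D
            "proline": {"2D": (300.0, 330.0), "3D": (300.0, 200.0)},
        },
    )


def simulate_mid(f: float, n: int, model: str = "binomial-mixture") -> np.ndarray:
    """True MID for labeled-molecule fraction ``f`` over n carbons.

    ``binomial-mixture``: each carbon independently labeled with probability
    f (Binomial(n, f) mass function).  ``two-pool``: a fraction f of fully
    labeled molecules mixed with unlabeled ones.  Total carbon contribution
    equals f exactly in both models.
    """
    if not 0 <= f <= 1:
        raise ValueError(f"labeled fraction must be in [0, 1], got {f}")
    if model == "binomial-mixture":
        return scipy.stats.binom.pmf(np.arange(n + 1), n, f)
    if model == "two-pool":
        mid = np.zeros(n + 1)
        mid[0] = 1 - f
        mid[n] += f
        return mid
    raise ValueError(f"unknown labeling model {model!r}")


def forward_measure(
    true_mid: np.ndarray,
    fragment: FragmentSpec,
    isotopes: IsotopeTable | None = None,
    purity: TracerPurity | None = None,
    noise: NoiseModel | None = None,
    rng: np.random.Generator | None = None,
    total_signal: float = 1e6,
) -> RawMID:
    """Forward model: convolve a true MID with natural abundance and noise.

    Areas are proportional to ``CorrectionMatrix · true_mid`` scaled by
    ``total_signal`` and perturbed per mass by log-normal multiplicative
    noise of the model's σ.  Reproducible for a fixed generator state.
    """
    if noise is None:
        noise = NoiseModel(sigma=0.0)
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    cm = build_correction_matrix(fragment, isotopes, purity)
    expected = cm.matrix @ np.asarray(true_mid, dtype=float)
    factors = rng.lognormal(0.0, noise.sigma, size=len(expected)) if noise.sigma > 0 else 1.0
    return RawMID(fragment.metabolite, expected * total_signal * factors)


def simulate_level_table(
    true_folds: Mapping[str, float],
    sigma: float,
    n_replicates: int,
    rng: np.random.Generator,
    control: str = "control",
    treated: str = "treated",
    base_level: float = 1.0,
) -> pd.DataFrame:
    """Replicate-level table with planted fold effects and log-normal noise.

    ``true_folds`` maps metabolite → treated/control fold (1.0 = planted
    null).  Returns long-format columns (metabolite, condition, value) for
    :func:`~tracermet.expression_stats.differential_filter`.
    """
    rows = []
    for metabolite, fold in true_folds.items():
        for condition, mean in ((control, base_level), (treated, base_level * fold)):
            values = mean * rng.lognormal(0.0, sigma, size=n_replicates)
            rows.extend(
                {"metabolite": metabolite, "condition": condition, "value": v}
                for v in values
            )
    return pd.DataFrame(rows)


@dataclasses.dataclass(frozen=True)
class StudyBundle:
    """All generated inputs plus the planted ground truth."""

    design: StudyDesign
    noise: NoiseModel
    areas: pd.DataFrame        # sample, metabolite, mass_shift, area
    samples: pd.DataFrame      # sample sheet with normalization denominators
    media: pd.DataFrame        # fresh/spent media concentrations
    ct: pd.DataFrame           # qPCR cycle thresholds
    ground_truth: pd.DataFrame # metabolite/gene, condition, true values

    def write(self, outdir) -> pd.DataFrame:
        """Write all TSVs to ``outdir``; return a manifest with checksums."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        names = {
            "areas.tsv": self.areas,
            "samples.tsv": self.samples,
            "media.tsv": self.media,
            "ct.tsv": self.ct,
            "ground_truth.tsv": self.ground_truth,
        }
        records = []
        for name, df in names.items():
            path = outdir / name
            df.to_csv(path, sep="\t", index=False)
            digest = hashlib.sha256(path.read_bytes()).hexdigest()
            records.append({"file": name, "sha256": digest})
        return pd.DataFrame(records)


def simulate_study(
    design: StudyDesign | None = None,
    noise: NoiseModel | None = None,
    fragments: Mapping[str, FragmentSpec] | None = None,
    isotopes: IsotopeTable | None = None,
) -> StudyBundle:
    """Generate a full study input bundle with planted ground truth.

    The master seed is fanned out per section (areas, media, Ct) via
    ``numpy`` seed sequences, so regenerating one section never perturbs
    another.
    """
    if design is None:
        design = default_study()
    if noise is None:
        noise = NoiseModel()
    if fragments is None:
        fragments = example_fragment_library()
    if isotopes is None:
        isotopes = IsotopeTable.default()
    purity = TracerPurity(design.purity) if design.purity is not None else None

    seq_areas, seq_media, seq_ct, seq_sheet = np.random.SeedSequence(noise.seed).spawn(4)
    rng_areas = np.random.default_rng(seq_areas)
    rng_media = np.random.default_rng(seq_media)
    rng_ct = np.random.default_rng(seq_ct)
    rng_sheet = np.random.default_rng(seq_sheet)

    sample_ids = {
        cond: [f"{cond}_r{i + 1}" for i in range(design.n_replicates)]
        for cond in design.conditions
    }

    area_rows, sheet_rows, truth_rows = [], [], []
    for cond in design.conditions:
        for sample in sample_ids[cond]:
            istd = float(1e5 * rng_sheet.lognormal(0.0, 0.05))
            biomass = float(design.biomass_mg * rng_sheet.lognormal(0.0, 0.05))
            sheet_rows.append(
                {
                    "sample": sample,
                    "condition": cond,
                    "replicate": int(sample.rsplit("_r", 1)[1]),
                    "tracer": design.tracer,
                    "purity": design.purity if design.purity is not None else "",
                    "istd_area": istd,
                    "biomass_mg": biomass,
                    "biomass_kind": design.biomass_kind,
                }
            )
            for spec in design.metabolites:
                fragment = fragments[spec.name]
                true_mid = simulate_mid(
                    spec.labeled_fraction[cond], fragment.n_carbons, spec.labeling_model
                )
                # total *observed* signal carries the planted level through
                # the internal-standard/biomass normalization chain; divide
                # out the truncation loss of masses above M+n so the summed
                # areas equal level·istd·biomass exactly in the noise-free case
                cm = build_correction_matrix(fragment, isotopes, purity)
                observed_fraction = float((cm.matrix @ true_mid).sum())
                total = spec.level[cond] * istd * biomass / observed_fraction
                raw = forward_measure(
                    true_mid, fragment, isotopes, purity, noise, rng_areas, total
                )
                area_rows.extend(
                    {
                        "sample": sample,
                        "metabolite": spec.name,
                        "mass_shift": shift,
                        "area": float(area),
                    }
                    for shift, area in enumerate(raw.areas)
                )

    for spec in design.metabolites:
        control_level = spec.level[design.control]
        for cond in design.conditions:
            truth_rows.append(
                {
                    "kind": "metabolite",
                    "name": spec.name,
                    "condition": cond,
                    "true_contribution": spec.labeled_fraction[cond],
                    "true_level": spec.level[cond],
                    "true_fold": spec.level[cond] / control_level,
                }
            )

    media_rows = []
    for metabolite, per_cond in design.media.items():
        for cond, (fresh, spent) in per_cond.items():
            for sample in sample_ids[cond]:
                jitter = rng_media.lognormal(0.0, noise.sigma) if noise.sigma > 0 else 1.0
                media_rows.append(
                    {
                        "sample": sample,
                        "metabolite": metabolite,
                        "condition": cond,
                        "conc_fresh_uM": fresh,
                        "conc_spent_uM": float(spent * jitter),
                        "volume_ml": design.media_volume_ml,
                        "span_h": design.media_span_h,
                    }
                )

    ct_rows = []
    ct_sd = 0.15  # cycle-to-cycle technical spread
    for cond in design.conditions:
        for sample in sample_ids[cond]:
            ref_ct = float(18.0 + rng_ct.normal(0.0, ct_sd))
            ct_rows.append(
                {"sample": f"q_{sample}", "condition": cond, "gene": "RPL19", "ct": ref_ct}
            )
            for gene, per_cond in design.gene_dct.items():
                ct_rows.append(
                    {
                        "sample": f"q_{sample}",
                        "condition": cond,
                        "gene": gene,
                        "ct": float(ref_ct + per_cond[cond] + rng_ct.normal(0.0, ct_sd)),
                    }
                )
    for gene, per_cond in design.gene_dct.items():
        for cond in design.conditions:
            truth_rows.append(
                {
                    "kind": "gene",
                    "name": gene,
                    "condition": cond,
                    "true_contribution": "",
                    "true_level": "",
                    "true_fold": 2.0 ** -(per_cond[cond] - per_cond[design.control]),
                }
            )

    return StudyBundle(
        design=design,
        noise=noise,
        areas=pd.DataFrame(area_rows),
        samples=pd.DataFrame(sheet_rows),
        media=pd.DataFrame(media_rows),
        ct=pd.DataFrame(ct_rows),
        ground_truth=pd.DataFrame(truth_rows),
    )


def write_chromatograms(
    bundle: StudyBundle,
    outdir,
    peak_sd_s: float = 4.0,
    window_s: float = 20.0,
    sampling_hz: float = 2.0,
    retention_start_s: float = 300.0,
    retention_step_s: float = 60.0,
) -> tuple[Path, Path]:
    """Render the bundle's areas as Gaussian-peak ion chromatograms.

    Each metabolite gets a retention time; every ion of a sample is written
    as a Gaussian of the corresponding area on a flat (optionally drifting)
    baseline.  Writes ``chromatograms.tsv`` and matching ``bounds.tsv`` and
    returns their paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence(bundle.noise.seed).spawn(5)[4])
    metabolites = sorted(bundle.areas["metabolite"].unique())
    retention = {
        m: retention_start_s + i * retention_step_s for i, m in enumerate(metabolites)
    }
    rows = []
    bounds_rows = []
    for m in metabolites:
        rt = retention[m]
        bounds_rows.append(
            {"metabolite": m, "t_start_s": rt - window_s, "t_end_s": rt + window_s}
        )
    times_rel = np.arange(-window_s - 5, window_s + 5 + 1e-9, 1.0 / sampling_hz)
    for row in bundle.areas.itertuples(index=False):
        rt = retention[row.metabolite]
        t = rt + times_rel
        peak = row.area / (peak_sd_s * np.sqrt(2 * np.pi)) * np.exp(
            -0.5 * (times_rel / peak_sd_s) ** 2
        )
        if bundle.noise.baseline_drift > 0:
            drift = bundle.noise.baseline_drift * (
                rng.uniform(-1, 1) + rng.uniform(-1, 1) * times_rel / window_s
            )
            peak = peak + drift
        rows.extend(
            {
                "sample": row.sample,
                "metabolite": row.metabolite,
                "mass_shift": row.mass_shift,
                "time_s": float(ti),
                "intensity": float(pi),
            }
            for ti, pi in zip(t, peak)
        )
    chrom_path = outdir / "chromatograms.tsv"
    bounds_path = outdir / "bounds.tsv"
    pd.DataFrame(rows).to_csv(chrom_path, sep="\t", index=False)
    pd.DataFrame(bounds_rows).to_csv(bounds_path, sep="\t", index=False)
    return chrom_path, bounds_path
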