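"""Synthetic-data generator for every assay in the pipeline.

Emulates the statistical structure of the real experiments — label-swapped
SILAC duplicate tables with decoy rows, replicated mutant-vs-WT captures
with a replicate-level bait offset, four-point exchange time courses, and
per-field nuclei point patterns — together with the planted ground truth,
so the full pipeline is testable without any external download.

The planted cast mirrors the biological setting: a 7-member cytoplasmic RNP
module (the ORF2p bait, ORF1p, and RNA-dependent partners such as MOV10 and
UPF1) and a 16-member nuclear module containing a tightly co-partitioning
PURA/PURB/PCNA triple.  Measurement noise acts on the logit scale so
fractions stay inside (0, 1); the default 0.15-logit SD corresponds to
about 0.037 on the fraction scale near 0.5, a typical replicate spread for
well-quantified SILAC ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError
from .nuclei import NucleiField
from .quant_io import LabelDesign, ProteinGroupTable

__all__ = [
    "SyntheticDesign",
    "PlantedTruth",
    "CYTOPLASMIC_MODULE",
    "NUCLEAR_MODULE",
    "TIGHT_TRIPLE",
    "simulate_swap_experiment",
    "simulate_mutant_experiment",
    "simulate_timecourse",
    "simulate_profile_set",
    "simulate_nuclei_fields",
]

#: bait-anchored cytoplasmic RNP module (bait first)
CYTOPLASMIC_MODULE = ("ORF2", "ORF1", "MOV10", "UPF1", "ZCCHC3", "PABPC1", "PABPC4")

#: nuclear module; the first three form the tightly co-partitioning triple
NUCLEAR_MODULE = (
    "PURA", "PURB", "PCNA", "TOP1", "PARP1", "HSPA8", "HSPA1A", "IPO7",
    "TROVE2", "SSB", "RUVBL1", "RUVBL2", "NAP1L1", "NAP1L4", "TOP2B", "MATR3",
)

TIGHT_TRIPLE = ("PURA", "PURB", "PCNA")

#: proteins released by RNase digestion (RNA-dependent interactors) with the
#: relative magnitude of their displacement; UPF1 is planted at ~62% of the
#: MOV10/ORF1 sensitivity, mirroring its partial RNA dependence
RNASE_SENSITIVE_SCALES = {"ORF1": 1.0, "MOV10": 1.0, "ZCCHC3": 1.0, "UPF1": 0.62}

RNASE_SENSITIVE = tuple(RNASE_SENSITIVE_SCALES)

#: true elution fractions in the split-tandem assay (anchor ORF1 near 1,
#: bait ~quarter bound, nuclear set predominantly unbound)
SPLIT_FRACTIONS = {
    "ORF1": 0.95, "ORF2": 0.26, "UPF1": 0.55, "MOV10": 0.70, "ZCCHC3": 0.72,
    "PABPC1": 0.60, "PABPC4": 0.61,
    "PURA": 0.13, "PURB": 0.13, "PCNA": 0.13, "TOP1": 0.20, "PARP1": 0.25,
    "HSPA8": 0.30, "HSPA1A": 0.31, "IPO7": 0.28, "TROVE2": 0.18, "SSB": 0.22,
    "RUVBL1": 0.33, "RUVBL2": 0.34, "NAP1L1": 0.24, "NAP1L4": 0.26,
    "TOP2B": 0.16, "MATR3": 0.21,
}


@dataclass
class SyntheticDesign:
    """All knobs of the generator; a pure function of (design, seed).

    Defaults are the study conditions every calibration and recovery test
    runs under; see docs/methods.md for the reasoning behind each value.
    """

    seed: int
    n_background: int = 300
    noise_sd: float = 0.15            # logit-scale replicate noise
    rnase_displacement: float = 0.20  # radial displacement of sensitive proteins
    triple_jitter_sd: float = 0.02    # extra logit jitter inside the tight triple
    mutant_delta: float = 0.15        # |shift| of planted classes on the fraction scale
    mutant_sigma: float = 0.05        # replicate noise, fraction scale
    bait_offset_range: float = 0.08   # replicate-level bait offset, uniform +-
    n_contaminants: int = 5
    n_reverse: int = 5
    n_one_peptide: int = 5
    bait: str = "ORF2"
    anchor: str = "ORF1"
    timepoints: tuple[float, ...] = (0.0, 30.0, 300.0, 1800.0)
    exchange_noise_sd: float = 0.02
    #: (rate 1/s, baseline, n proteins) per kinetic class, most stable first
    exchange_classes: tuple[tuple[float, float, int], ...] = (
        (1e-4, 0.20, 10),
        (1e-3, 0.10, 10),
        (1e-2, 0.05, 10),
    )

    def __post_init__(self) -> None:
        if self.seed is None:
            raise DomainError("a seed is mandatory")
        if not 0 < self.noise_sd:
            raise DomainError("noise_sd must be positive")
        for frac in SPLIT_FRACTIONS.values():
            assert 0.0 < frac < 1.0
        for rate, b, n in self.exchange_classes:
            if rate < 0 or not 0.0 <= b <= 1.0 or n < 1:
                raise DomainError("invalid exchange class parameters")
        if not 0.0 < self.mutant_sigma and self.mutant_delta >= 0:
            raise DomainError("invalid mutant parameters")


@dataclass
class PlantedTruth:
    """Ground truth accompanying each simulated dataset."""

    modules: dict[str, str] = field(default_factory=dict)   # protein -> module label
    params: dict = field(default_factory=dict)              # assay-specific truth
    nuclei_pairs: dict[str, list[tuple[int, int]]] = field(default_factory=dict)


def _logit(p):
    return np.log(p / (1.0 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def _background_names(n: int) -> list[str]:
    return [f"BG{i:04d}" for i in range(1, n + 1)]


def _module_map(design: SyntheticDesign) -> dict[str, str]:
    mods = {p: "cytoplasmic" for p in CYTOPLASMIC_MODULE}
    mods.update({p: "nuclear" for p in NUCLEAR_MODULE})
    mods.update({p: "background" for p in _background_names(design.n_background)})
    return mods


def _decoy_rows(design: SyntheticDesign, rng: np.random.Generator) -> list[dict]:
    rows = []
    for i in range(design.n_contaminants):
        rows.append(dict(gene_symbol=f"CONT{i:02d}", ratio_hl=float(rng.lognormal(0, 0.5)),
                         razor_unique_peptides=int(rng.integers(2, 20)),
                         is_contaminant=True, is_reverse=False))
    for i in range(design.n_reverse):
        rows.append(dict(gene_symbol=f"REV{i:02d}", ratio_hl=float(rng.lognormal(0, 0.5)),
                         razor_unique_peptides=int(rng.integers(2, 20)),
                         is_contaminant=False, is_reverse=True))
    for i in range(design.n_one_peptide):
        rows.append(dict(gene_symbol=f"ONE{i:02d}", ratio_hl=float(rng.lognormal(0, 0.5)),
                         razor_unique_peptides=1,
                         is_contaminant=False, is_reverse=False))
    return rows


def _table_from_fractions(
    fractions: pd.Series,
    design: SyntheticDesign,
    label_design: LabelDesign,
    condition_a: str,
    sample_id: str,
    rng: np.random.Generator,
) -> ProteinGroupTable:
    """Emit a protein-group table whose H/L ratios encode condition-A fractions."""
    f = fractions.to_numpy(dtype=float)
    h = f if label_design.heavy == condition_a else 1.0 - f
    rows = [
        dict(
            gene_symbol=g,
            ratio_hl=float(hh / (1.0 - hh)),
            razor_unique_peptides=int(rng.integers(2, 40)),
            is_contaminant=False,
            is_reverse=False,
        )
        for g, hh in zip(fractions.index, h)
    ]
    rows.extend(_decoy_rows(design, rng))
    df = pd.DataFrame(rows)
    df["group_members"] = df["gene_symbol"]
    return ProteinGroupTable(df, sample_id=sample_id, design=label_design)


def simulate_swap_experiment(
    design: SyntheticDesign,
    assay: str,
    seed: int | None = None,
    noise_sd: float | None = None,
    rnase_displacement: float | None = None,
    sensitive_scales: dict[str, float] | None = None,
) -> tuple[ProteinGroupTable, ProteinGroupTable, PlantedTruth]:
    """Two label-swapped protein-group tables for the RNase or split assay.

    ``assay``: "rnase" (conditions BSA vs RNase; sensitive proteins displaced
    toward BSA on both axes) or "split" (conditions elution vs supernatant;
    per-protein elution fractions, with the PURA/PURB/PCNA triple sharing a
    common noise draw so its co-partitioning is genuinely tight).
    """
    if assay not in ("rnase", "split"):
        raise DomainError(f"unknown assay {assay!r}")
    rng = np.random.default_rng(design.seed if seed is None else seed)
    sd = design.noise_sd if noise_sd is None else noise_sd
    modules = _module_map(design)
    proteins = list(modules)

    if assay == "rnase":
        disp = design.rnase_displacement if rnase_displacement is None else rnase_displacement
        scales = dict(RNASE_SENSITIVE_SCALES) if sensitive_scales is None else sensitive_scales
        per_axis = disp / np.sqrt(2.0)
        true = pd.Series(
            {p: 0.5 + scales.get(p, 0.0) * per_axis for p in proteins}
        )
        condition_a, condition_b = "BSA", "RNase"
        sensitive = {p: scales.get(p, 0.0) > 0.0 for p in proteins}
        truth_params = {
            "sensitive": sensitive,
            "displacement": disp,
            "scales": scales,
        }
    else:
        bg = {
            p: v
            for p, v in zip(
                _background_names(design.n_background),
                rng.uniform(0.08, 0.92, design.n_background),
            )
        }
        true = pd.Series({**SPLIT_FRACTIONS, **bg})[proteins]
        condition_a, condition_b = "elution", "supernatant"
        truth_params = {"elution_fraction": true.to_dict(), "tight_triple": TIGHT_TRIPLE}

    tables = []
    for mix, ld in enumerate(
        (
            LabelDesign(heavy=condition_a, light=condition_b),
            LabelDesign(heavy=condition_b, light=condition_a),
        )
    ):
        z = _logit(true.to_numpy())
        noise = rng.normal(0.0, sd, len(true))
        if assay == "split":
            # shared draw inside the tight triple + small individual jitter
            shared = rng.normal(0.0, sd)
            for p in TIGHT_TRIPLE:
                i = true.index.get_loc(p)
                noise[i] = shared + rng.normal(0.0, design.triple_jitter_sd)
        observed = pd.Series(_expit(z + noise), index=true.index)
        tables.append(
            _table_from_fractions(
                observed, design, ld, condition_a,
                sample_id=f"{assay}_mix{mix + 1}", rng=rng,
            )
        )
    truth = PlantedTruth(modules=modules, params=truth_params)
    return tables[0], tables[1], truth


#: sign of the planted mean shift (on the heavy-fraction scale) per module/mutant
_MUTANT_SIGNS = {
    ("cytoplasmic", "EN"): -1.0,
    ("cytoplasmic", "RT"): +1.0,
    ("nuclear", "EN"): +1.0,
    ("nuclear", "RT"): -1.0,
}


def simulate_mutant_experiment(
    design: SyntheticDesign,
    mutant: str,
    n_replicates: int = 3,
    seed: int | None = None,
    delta: float | None = None,
    sigma: float | None = None,
) -> tuple[list[ProteinGroupTable], PlantedTruth]:
    """Replicate tables of a light-labelled mutant against heavy-labelled WT.

    The planted classes shift in opposite directions in the two mutants
    (cytoplasmic down in EN and up in RT; nuclear the reverse); a uniform
    replicate-level bait offset exercises the downstream shift
    normalization; the bait itself sits exactly at 0.5 + offset.
    """
    if mutant not in ("EN", "RT"):
        raise DomainError(f"mutant must be 'EN' or 'RT', got {mutant!r}")
    rng = np.random.default_rng(design.seed if seed is None else seed)
    dh = design.mutant_delta if delta is None else delta
    sg = design.mutant_sigma if sigma is None else sigma
    modules = _module_map(design)
    proteins = list(modules)
    true_h = pd.Series(
        {p: 0.5 + _MUTANT_SIGNS.get((modules[p], mutant), 0.0) * dh for p in proteins}
    )
    tables = []
    for rep in range(n_replicates):
        offset = float(rng.uniform(-design.bait_offset_range, design.bait_offset_range))
        h = np.clip(true_h.to_numpy() + offset + rng.normal(0.0, sg, len(true_h)),
                    0.005, 0.995)
        obs = pd.Series(h, index=true_h.index)
        obs.loc[design.bait] = 0.5 + offset
        tables.append(
            _table_from_fractions(
                obs, design, LabelDesign(heavy="WT", light=mutant), "WT",
                sample_id=f"{mutant}_rep{rep + 1}", rng=rng,
            )
        )
    truth = PlantedTruth(
        modules=modules,
        params={"mutant": mutant, "delta": dh,
                "true_shifted_mean": true_h.to_dict()},
    )
    return tables, truth


def simulate_timecourse(
    design: SyntheticDesign, seed: int | None = None
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Heavy-fraction decay matrix h(t) = (1-b)*exp(-k t) + b with planted classes.

    t = 0 is the untreated capture and is noiseless at h = 1 by convention;
    later points carry truncated-normal noise.  Returns proteins x times.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    times = np.asarray(design.timepoints, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise DomainError("time points must be strictly increasing")
    # most stable class first: nuclear proteins, then the cytoplasmic RNP,
    # then background identifiers once the named roster is exhausted
    roster = list(NUCLEAR_MODULE) + list(CYTOPLASMIC_MODULE) + _background_names(
        design.n_background
    )
    cursor = 0
    rows, classes, kinetics = [], {}, {}
    for ci, (rate, b, n) in enumerate(design.exchange_classes, start=1):
        for j in range(n):
            name = roster[cursor] if cursor < len(roster) else f"C{ci}P{j + 1:02d}"
            cursor += 1
            h = (1.0 - b) * np.exp(-rate * times) + b
            h[1:] = np.clip(h[1:] + rng.normal(0.0, design.exchange_noise_sd,
                                               len(times) - 1), 0.0, 1.0)
            h[0] = 1.0
            rows.append(pd.Series(h, index=times, name=name))
            classes[name] = ci
            kinetics[name] = (rate, b)
    matrix = pd.DataFrame(rows)
    matrix.index.name = "protein"
    truth = PlantedTruth(params={"class": classes, "kinetics": kinetics})
    return matrix, truth


def simulate_profile_set(
    n_modules: int = 5,
    proteins_per_module: int = 8,
    n_experiments: int = 4,
    features_per_experiment: int = 3,
    sigma: float = 0.05,
    missing_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[dict[str, pd.DataFrame], PlantedTruth]:
    """Planted-module multi-experiment profiles for the integration stage.

    Each module carries its own signature vector per experiment; protein
    profiles are the module signature plus N(0, sigma) noise.  With
    ``missing_fraction`` > 0, that fraction of (protein, experiment) cells
    is dropped, exercising the shared-experiment / missing-pair logic.
    """
    rng = np.random.default_rng(seed)
    modules = {}
    frames: dict[str, pd.DataFrame] = {}
    names = [
        f"M{m + 1}P{j + 1:02d}"
        for m in range(n_modules)
        for j in range(proteins_per_module)
    ]
    for p in names:
        modules[p] = f"module{int(p[1:p.index('P')])}"
    signatures = rng.uniform(
        0.0, 1.0, size=(n_modules, n_experiments, features_per_experiment)
    )
    for e in range(n_experiments):
        data = {}
        for m in range(n_modules):
            for j in range(proteins_per_module):
                p = f"M{m + 1}P{j + 1:02d}"
                if missing_fraction > 0 and rng.random() < missing_fraction:
                    continue
                data[p] = signatures[m, e] + rng.normal(
                    0.0, sigma, features_per_experiment
                )
        frames[f"exp{e + 1}"] = pd.DataFrame.from_dict(data, orient="index")
    truth = PlantedTruth(modules=modules, params={"sigma": sigma})
    return frames, truth


def simulate_nuclei_fields(
    n_fields: int = 20,
    field_size: tuple[float, float] = (500.0, 500.0),
    density: float = 1e-4,
    positive_fraction: float = 0.1,
    pair_mode: str = "random",
    n_pairs_per_field: int = 2,
    displacement: float = 10.0,
    jitter_sd: float = 0.0,
    seed: int = 0,
) -> tuple[list[NucleiField], PlantedTruth]:
    """Per-field spatial Poisson nuclei with random or planted-pair positives.

    ``pair_mode="random"`` flags each nucleus positive independently (the
    null configuration); ``"daughter_pairs"`` adds ``n_pairs_per_field``
    positive pairs at the stated displacement (post-mitotic daughter nuclei),
    on top of an all-negative Poisson background.  The default density 1e-4
    nuclei/µm² gives a mean nearest-neighbour spacing of 0.5/sqrt(density)
    = 50 µm.
    """
    area = field_size[0] * field_size[1]
    if density * area < 2:
        raise DomainError("expected nucleus count per field must be >= 2")
    if pair_mode not in ("random", "daughter_pairs"):
        raise DomainError(f"unknown pair_mode {pair_mode!r}")
    rng = np.random.default_rng(seed)
    fields, truth_pairs = [], {}
    for fi in range(n_fields):
        fid = f"F{fi + 1:03d}"
        n = max(2, int(rng.poisson(density * area)))
        pts = np.column_stack(
            [rng.uniform(0, field_size[0], n), rng.uniform(0, field_size[1], n)]
        )
        if pair_mode == "random":
            pos = rng.random(n) < positive_fraction
            fields.append(NucleiField(fid, pts, pos))
            continue
        pos = np.zeros(n, dtype=bool)
        pairs = []
        margin = displacement / 2.0 + 1.0
        for _ in range(n_pairs_per_field):
            cx = rng.uniform(margin, field_size[0] - margin)
            cy = rng.uniform(margin, field_size[1] - margin)
            theta = rng.uniform(0, 2 * np.pi)
            offset = (displacement / 2.0) * np.array([np.cos(theta), np.sin(theta)])
            p1 = np.array([cx, cy]) + offset
            p2 = np.array([cx, cy]) - offset
            if jitter_sd > 0:
                p1 = p1 + rng.normal(0, jitter_sd, 2)
                p2 = p2 + rng.normal(0, jitter_sd, 2)
            pts = np.vstack([pts, p1, p2])
            pos = np.concatenate([pos, [True, True]])
            pairs.append((len(pts) - 2, len(pts) - 1))
        fields.append(NucleiField(fid, pts, pos))
        truth_pairs[fid] = pairs
    truth = PlantedTruth(
        params={
            "pair_mode": pair_mode,
            "displacement": displacement,
            "density": density,
            "field_size": list(field_size),
        },
        nuclei_pairs=truth_pairs,
    )
    return fields, truth
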