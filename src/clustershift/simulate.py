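"""Synthetic time-course RNA-seq generator with planted temporal structure.

The generator emulates a two-tissue amputation time course (0, 3, 8 dpa) with a
control and an HDAC-inhibitor arm, two pooled replicates per condition, and the
homeostatic 0-dpa baseline shared by both arms.  Counts are negative-binomial
around ``lib_s · baseline · 2^(amplitude · archetype(t) + N(0, noise_sd))``.

Every gene follows one of a small library of z-scored temporal archetypes
(monotone up/down, late up/down, early up/down, transient peak/dip, ...).  A
configurable fraction of genes is planted with a *premature shift*: under the
inhibitor their 3-dpa expected level equals their control 8-dpa level, i.e. the
"late up" blastema-stage profile becomes the "early up" profile.  The returned
:class:`GroundTruth` records archetype assignments per arm, the shifted genes,
planted/decoy gene sets and cell-type signature abundance multipliers, so the
whole downstream pipeline can be scored against known answers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import CountMatrix, SampleTable, ValidationError

# canonical trend templates, evaluated on time normalized to [0, 1]
_TEMPLATES = (
    ("monotone_up", lambda x: x),
    ("monotone_down", lambda x: -x),
    ("late_up", lambda x: (x >= 1.0).astype(float)),
    ("late_down", lambda x: -(x >= 1.0).astype(float)),
    ("early_up", lambda x: (x > 0.0).astype(float)),
    ("early_down", lambda x: -(x > 0.0).astype(float)),
    ("transient_peak", lambda x: 1.0 - np.abs(2.0 * x - 1.0)),
    ("transient_dip", lambda x: np.abs(2.0 * x - 1.0) - 1.0),
)

LATE_UP = 2    # control archetype of planted shift genes
EARLY_UP = 4   # inhibitor archetype of planted shift genes


@dataclass
class SimulationConfig:
    """Study design and noise model for the synthetic generator.

    Defaults mirror the emulated experiment: 2 tissues × (0, 3, 8) dpa ×
    (control, inhibitor) with the 0-dpa baseline shared, 2 replicates,
    archetype amplitude 2 on the log2 scale, and 10% of genes given a
    premature shift.
    """

    n_genes: int = 2000
    n_archetypes: int = 8
    timepoints: tuple = (0, 3, 8)
    treatments: tuple = ("control", "inhibitor")
    tissues: tuple = ("epidermis", "soft_tissue")
    n_replicates: int = 2
    frac_shifted: float = 0.1
    frac_dynamic: float = 0.3
    baseline_mean: float = 1000.0
    dispersion: float = 0.0025
    amplitude: float = 2.0
    library_size_factors: tuple | None = None
    noise_sd: float = 0.25
    n_gene_sets: int = 20
    set_size_range: tuple = (20, 80)
    n_cell_types: int = 3
    signature_size: int = 20
    archetype_separation: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_archetypes < 2:
            raise ValidationError("n_genes must be positive and n_archetypes >= 2")
        if len(self.timepoints) < 3:
            raise ValidationError("at least 3 timepoints required")
        if not isinstance(self.n_replicates, (int, np.integer)) or self.n_replicates < 1:
            raise ValidationError("n_replicates must be a positive integer")
        if not 0.0 <= self.frac_shifted <= 1.0:
            raise ValidationError("frac_shifted must lie in [0, 1]")
        if not 0.0 <= self.frac_dynamic <= 1.0:
            raise ValidationError("frac_dynamic must lie in [0, 1]")
        if self.frac_shifted > self.frac_dynamic:
            raise ValidationError("frac_shifted cannot exceed frac_dynamic")
        if self.baseline_mean <= 0 or self.dispersion < 0 or self.noise_sd < 0:
            raise ValidationError("baseline_mean > 0, dispersion >= 0, noise_sd >= 0 required")
        if self.frac_shifted > 0 and self.n_archetypes <= EARLY_UP:
            raise ValidationError(
                "planting shifted genes requires n_archetypes >= 5 "
                "(both the late-up and early-up archetypes must exist)"
            )

    @property
    def n_shifted(self) -> int:
        return int(round(self.frac_shifted * self.n_genes))


@dataclass
class GroundTruth:
    """Record of everything the generator planted."""

    archetype_profiles: pd.DataFrame            # archetype × timepoint, z-scale
    gene_archetype: dict                        # treatment -> {gene: archetype index}
    shifted_genes: list
    planted_sets: dict = field(default_factory=dict)   # name -> {genes, is_enriched_in_transition}
    signature_truth: dict = field(default_factory=dict)  # cell type -> {sample: multiplier}

    def to_json(self, path: str | Path) -> None:
        obj = {
            "archetype_profiles": self.archetype_profiles.to_dict(orient="split"),
            "gene_archetype": self.gene_archetype,
            "shifted_genes": self.shifted_genes,
            "planted_sets": self.planted_sets,
            "signature_truth": self.signature_truth,
        }
        Path(path).write_text(json.dumps(obj, indent=1, default=str))


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd < 1e-12:
        raise ValidationError("degenerate (constant) archetype shape")
    return (v - v.mean()) / sd


def generate_archetypes(n_archetypes: int, timepoints: list | tuple,
                        separation: float = 0.5) -> pd.DataFrame:
    """Distinct z-scored temporal trend shapes (archetype × timepoint).

    The first eight rows are the canonical named trends; further rows (three
    timepoints only) are placed on the circle of z-scored 3-point profiles at
    angles kept at least ``separation`` away from every chosen shape.  Raises
    when more shapes are requested than can be packed at that separation.
    """
    if n_archetypes < 2:
        raise ValidationError("n_archetypes must be >= 2")
    tp = np.asarray(timepoints, dtype=float)
    if tp.size < 2:
        raise ValidationError("need at least 2 timepoints")
    # trends are shapes over ordinal stages, not absolute days
    x = np.arange(tp.size, dtype=float) / (tp.size - 1)
    rows: list[np.ndarray] = []
    names: list[str] = []
    for name, f in _TEMPLATES[:n_archetypes]:
        rows.append(_zscore(f(x)))
        names.append(name)
    if n_archetypes > len(_TEMPLATES):
        if tp.size != 3:
            raise ValidationError(
                f"at most {len(_TEMPLATES)} archetypes supported for "
                f"{tp.size} timepoints"
            )
        # z-scored 3-point profiles live on a circle of radius sqrt(2):
        # pack extra shapes at angles respecting the separation
        e1 = _zscore(np.array([0.0, 1.0, 2.0])) / np.sqrt(2)
        e2 = np.cross(np.ones(3) / np.sqrt(3), e1)
        max_n = int(np.floor(2 * np.pi / (2 * np.arcsin(separation / (2 * np.sqrt(2))))))
        if n_archetypes > max_n:
            raise ValidationError(
                f"cannot construct {n_archetypes} shapes with separation "
                f"{separation} from 3 timepoints; maximum is {max_n}"
            )
        for theta in np.linspace(0, 2 * np.pi, 720, endpoint=False):
            if len(rows) >= n_archetypes:
                break
            cand = np.sqrt(2) * (np.cos(theta) * e1 + np.sin(theta) * e2)
            if all(np.linalg.norm(cand - r) >= separation for r in rows):
                rows.append(cand)
                names.append(f"shape_{len(rows)}")
        if len(rows) < n_archetypes:
            raise ValidationError(
                f"cannot construct {n_archetypes} shapes with separation "
                f"{separation} from 3 timepoints; achieved {len(rows)}"
            )
    mat = pd.DataFrame(np.vstack(rows), index=names, columns=list(timepoints))
    d = _min_pairwise_distance(mat.to_numpy())
    if d < separation:
        raise ValidationError(
            f"canonical shapes violate separation {separation} (min distance {d:.3f})"
        )
    return mat


def _min_pairwise_distance(m: np.ndarray) -> float:
    from scipy.spatial.distance import pdist
    return float(pdist(m).min())


def _sample_ids(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    t0 = config.timepoints[0]
    for tissue in config.tissues:
        for rep in range(1, config.n_replicates + 1):
            rows.append((f"{tissue}_{t0}dpa_control_r{rep}", tissue, t0, "control", rep))
        for tp in config.timepoints[1:]:
            for treat in config.treatments:
                for rep in range(1, config.n_replicates + 1):
                    rows.append((f"{tissue}_{tp}dpa_{treat}_r{rep}", tissue, tp, treat, rep))
    df = pd.DataFrame(rows, columns=["sample", "tissue", "timepoint_dpa", "treatment", "replicate"])
    return df.set_index("sample")


def simulate_counts(config: SimulationConfig) -> tuple[CountMatrix, SampleTable, GroundTruth]:
    """Draw the count matrix, sample table and ground-truth record.

    Shifted genes follow the late-up archetype under control; under the
    inhibitor their 3-dpa expected value is moved to the control 8-dpa value
    (the early-up archetype).  Signature genes are flat in time and scaled by
    the planted per-sample abundance multipliers of their cell type.
    ``dispersion == 0`` is the deterministic limit: counts are rounded means.
    """
    rng = np.random.default_rng([config.seed, 0])
    archetypes = generate_archetypes(config.n_archetypes, config.timepoints,
                                     config.archetype_separation)
    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    samples = _sample_ids(config)
    sample_table = SampleTable(samples)
    n_sig = config.n_cell_types * config.signature_size
    if n_sig > config.n_genes:
        raise ValidationError("requested signatures exceed available genes")

    # gene roles: signature genes first (flat), then shifted, then background
    sig_genes = genes[:n_sig]
    n_shift = config.n_shifted
    shifted = genes[n_sig:n_sig + n_shift]
    if n_sig + n_shift > config.n_genes:
        raise ValidationError("frac_shifted and signatures together exceed n_genes")
    background = genes[n_sig + n_shift:]

    arch_control = np.empty(config.n_genes, dtype=int)
    arch_inhib = np.empty(config.n_genes, dtype=int)
    arch_control[:n_sig] = -1  # signature genes: flat, no archetype
    arch_inhib[:n_sig] = -1
    arch_control[n_sig:n_sig + n_shift] = LATE_UP
    arch_inhib[n_sig:n_sig + n_shift] = EARLY_UP
    # only a minority of the transcriptome is temporally dynamic; the rest
    # stays flat at baseline (archetype -1)
    n_dyn_bg = max(0, int(round(config.frac_dynamic * config.n_genes)) - n_shift)
    n_dyn_bg = min(n_dyn_bg, len(background))
    bg_arch = np.full(len(background), -1)
    dyn_idx = rng.choice(len(background), size=n_dyn_bg, replace=False)
    bg_arch[dyn_idx] = rng.integers(0, config.n_archetypes, size=n_dyn_bg)
    arch_control[n_sig + n_shift:] = bg_arch
    arch_inhib[n_sig + n_shift:] = bg_arch

    # per-sample expected log2 offsets
    tp_index = {tp: i for i, tp in enumerate(config.timepoints)}
    arch_arr = archetypes.to_numpy()
    lib = (np.ones(len(samples)) if config.library_size_factors is None
           else np.asarray(config.library_size_factors, dtype=float))
    if lib.size != len(samples):
        raise ValidationError(
            f"library_size_factors length {lib.size} != {len(samples)} samples"
        )
    if (lib <= 0).any():
        raise ValidationError("library size factors must be positive")

    signatures, multipliers = generate_signatures(config)

    mu = np.empty((config.n_genes, len(samples)))
    sig_mult = np.ones((config.n_genes, len(samples)))
    gene_pos = {g: i for i, g in enumerate(genes)}
    for ct, sig_list in signatures.items():
        gi = [gene_pos[g] for g in sig_list]
        for j, s in enumerate(samples.index):
            sig_mult[gi, j] = multipliers[ct][s]
    for j, (s, row) in enumerate(samples.iterrows()):
        ti = tp_index[row["timepoint_dpa"]]
        arch = arch_control if row["treatment"] == "control" else arch_inhib
        prof = np.where(arch >= 0, arch_arr[np.maximum(arch, 0), ti], 0.0)
        mu[:, j] = lib[j] * config.baseline_mean * sig_mult[:, j] \
            * 2.0 ** (config.amplitude * prof)
    if config.noise_sd > 0:
        mu = mu * 2.0 ** rng.normal(0.0, config.noise_sd, size=mu.shape)

    if config.dispersion == 0:
        counts = np.rint(mu).astype(np.int64)
    else:
        r = 1.0 / config.dispersion
        counts = rng.negative_binomial(r, r / (r + mu)).astype(np.int64)

    lengths = pd.Series(
        np.exp(rng.uniform(np.log(500.0), np.log(5000.0), size=config.n_genes)),
        index=genes, name="length",
    )
    cm = CountMatrix(pd.DataFrame(counts, index=genes, columns=samples.index), lengths)

    gt = GroundTruth(
        archetype_profiles=archetypes,
        gene_archetype={
            "control": {g: int(a) for g, a in zip(genes, arch_control) if a >= 0},
            "inhibitor": {g: int(a) for g, a in zip(genes, arch_inhib) if a >= 0},
        },
        shifted_genes=list(shifted),
        signature_truth={ct: {s: float(multipliers[ct][s]) for s in samples.index}
                         for ct in signatures},
    )
    gt.planted_sets = generate_gene_sets(gt, config)
    gt.signatures = signatures  # type: ignore[attr-defined]
    return cm, sample_table, gt


def generate_gene_sets(ground_truth: GroundTruth, config: SimulationConfig) -> dict:
    """One planted set (>= 80% shifted genes, flagged) plus uniform decoy sets
    drawn from non-shifted genes; sizes within ``set_size_range``."""
    rng = np.random.default_rng([config.seed, 1])
    lo, hi = config.set_size_range
    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    shifted = list(ground_truth.shifted_genes)
    non_shifted = [g for g in genes if g not in set(shifted)]
    if hi > len(genes) or lo > len(genes) or lo > hi:
        raise ValidationError(
            f"set_size_range {config.set_size_range} infeasible for {len(genes)} genes"
        )
    sets: dict = {}
    if shifted and config.n_gene_sets > 0:
        # largest size in range that can still be >= 80% shifted genes
        feasible_max = min(hi, int(np.floor(len(shifted) / 0.8)))
        if feasible_max < lo:
            raise ValidationError(
                f"cannot plant a set within size range {config.set_size_range} "
                f"that is >=80% shifted genes from only {len(shifted)} shifted genes"
            )
        size = max(lo, min((lo + hi) // 2, feasible_max))
        n_core = min(len(shifted), size)
        core = list(rng.choice(shifted, size=n_core, replace=False))
        filler = list(rng.choice(non_shifted, size=size - len(core), replace=False))
        sets["planted_shift_set"] = {
            "genes": sorted(core + filler),
            "is_enriched_in_transition": True,
        }
    n_decoys = max(config.n_gene_sets - len(sets), 0)
    for i in range(n_decoys):
        size = int(rng.integers(lo, hi + 1))
        if size > len(non_shifted):
            raise ValidationError(
                f"decoy set size {size} exceeds {len(non_shifted)} non-shifted genes"
            )
        members = sorted(rng.choice(non_shifted, size=size, replace=False))
        sets[f"decoy_set_{i + 1:03d}"] = {
            "genes": members,
            "is_enriched_in_transition": False,
        }
    return sets


def generate_signatures(config: SimulationConfig) -> tuple[dict, dict]:
    """Disjoint per-cell-type signature gene lists plus per-sample abundance
    multipliers (a temporal trajectory per cell type)."""
    if config.n_cell_types == 0:
        return {}, {}
    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    need = config.n_cell_types * config.signature_size
    if need > config.n_genes:
        raise ValidationError(
            f"{config.n_cell_types} signatures × {config.signature_size} genes "
            f"exceed {config.n_genes} available genes"
        )
    samples = _sample_ids(config)
    # trajectory templates over timepoints, cycled across cell types
    n_tp = len(config.timepoints)
    trajs = [
        np.linspace(1.0, 2.0, n_tp),       # expanding (e.g. cycling cells)
        np.linspace(2.0, 1.0, n_tp),       # contracting (mature populations)
        # transient expansion, slight decline afterwards (tie-free by design)
        np.array([1.0] + list(np.linspace(2.0, 1.8, n_tp - 1))),
    ]
    tp_index = {tp: i for i, tp in enumerate(config.timepoints)}
    signatures: dict = {}
    multipliers: dict = {}
    for k in range(config.n_cell_types):
        ct = f"celltype_{k + 1}"
        sig = genes[k * config.signature_size:(k + 1) * config.signature_size]
        signatures[ct] = list(sig)
        traj = trajs[k % len(trajs)]
        multipliers[ct] = {
            s: float(traj[tp_index[row["timepoint_dpa"]]])
            for s, row in samples.iterrows()
        }
    return signatures, multipliers


def write_dataset(outdir: str | Path, cm: CountMatrix, st: SampleTable,
                  gt: GroundTruth) -> dict:
    """Write counts/lengths/sample TSVs, gene-set and signature GMTs and the
    ground-truth JSON; returns the path map."""
    from .io import write_gmt
    from .expression import write_counts, write_sample_table
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.tsv",
        "lengths": out / "gene_lengths.tsv",
        "samples": out / "samples.tsv",
        "gene_sets": out / "gene_sets.gmt",
        "signatures": out / "signatures.gmt",
        "ground_truth": out / "ground_truth.json",
    }
    write_counts(cm, paths["counts"], paths["lengths"])
    write_sample_table(st, paths["samples"])
    write_gmt({k: v["genes"] for k, v in gt.planted_sets.items()}, paths["gene_sets"])
    sigs = getattr(gt, "signatures", {})
    write_gmt(sigs, paths["signatures"])
    gt.to_json(paths["ground_truth"])
    return {k: str(v) for k, v in paths.items()}
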