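"""Synthetic multi-tube cytometry cohorts with planted class structure.

The generator emulates the layout of a multi-panel AML screening dataset so
that every pipeline stage is testable without external data:

* Each sample is split into ``n_tubes`` staining tubes; every tube measures
  7 channels in the order FSC, SSC, FL1, FL2, FL3, FL4, FL5.  FSC, SSC and a
  CD45-like marker in the FL3 slot are shared by all tubes; the remaining
  four fluorescence channels carry tube-specific markers, so panels are
  mostly disjoint.  When at least four tubes are simulated, tube 1 is an
  isotype-control analog (its tube-specific channels are non-specific noise)
  and the last tube is an unstained analog (all five FL channels are noise).

* Cells are drawn from a diagonal-covariance Gaussian mixture over
  subpopulations.  Log-scale channel means follow on/off staining patterns
  (negative ~0.5, positive ~3.5 intensity units) chosen as binary codes with
  pairwise Hamming distance >= 2 per tube, which guarantees well-separated
  populations (pairwise L1 separation at least 4x the mean spread) in every
  informative tube.  FSC is generated on a raw linear scale with a large
  spread so that the downstream FSC rescaling step is genuinely exercised.

* One or more "blast-like" populations are rare at baseline; their abundance
  is multiplied by ``exp(effect_size)`` in AML samples (then renormalized).
  Within a class, samples differ through their multinomial cell draws (and
  cell counts); an optional logistic-normal abundance jitter — shared across
  the tubes of a sample, as aliquots of one specimen — can be switched on
  for harder, more heterogeneous cohorts.  ``effect_size = 0`` is an exact
  null: normal and AML samples are drawn from the same distribution.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .errors import CytoEmdError, ParameterError
from .io import CellMatrix, write_manifest, write_tube_csv

__all__ = [
    "PopulationTemplate",
    "CohortSpec",
    "make_template",
    "simulate_sample",
    "simulate_cohort",
]


class SeparationError(CytoEmdError, RuntimeError):
    """Well-separated population means could not be achieved."""


# generation constants (transformed-intensity units unless noted)
_NEG_MEAN, _POS_MEAN = 0.5, 3.5  # off/on staining levels, log scale
_MARKER_SD = 0.2
_SHARED_LEVELS = (0.4, 1.6, 2.8, 4.0)  # SSC / CD45 grid
_FSC_LATENT_RANGE = 0.15  # population FSC means span +-this, analysis scale
_FSC_LATENT_SD = 0.05
_FSC_OFFSET, _FSC_SCALE = 500.0, 2000.0  # raw linear FSC = offset + scale*latent
_NOISE_MEAN, _NOISE_SD = 0.5, 0.25  # non-specific control channels
_BLAST_BASELINE = 0.04  # baseline abundance of each blast-like population
# Optional per-sample logistic-normal abundance jitter (shared by all tubes
# of a sample).  Off by default: the cohort model ties every sample of a
# class to the same mixture weights, with multinomial cell sampling as the
# only within-class variation.  Turning jitter on makes cohorts harder
# (within-class EMD spread grows to the order of the class signal) and is
# intended for robustness exploration, not for the standard bench cohort.
_ABUNDANCE_JITTER_SD = 0.0

FL_SLOTS = (2, 3, 4, 5, 6)  # column indices of FL1..FL5
CD45_SLOT = 4  # FL3
MARKER_SLOTS = (2, 3, 5, 6)  # tube-specific FL channels


@dataclass
class PopulationTemplate:
    """Mixture definition shared by every sample of a cohort."""

    n_populations: int
    n_tubes: int
    channel_names: list[list[str]]  # per tube, 7 names
    means: np.ndarray  # (n_tubes, n_populations, 7), storage units
    sds: np.ndarray  # same shape, > 0
    baseline_abundance: np.ndarray  # (n_populations,), sums to 1
    aml_multiplier: np.ndarray  # (n_populations,)
    blast_populations: list[int]
    fsc_offset: float = _FSC_OFFSET
    fsc_scale: float = _FSC_SCALE
    abundance_jitter_sd: float = _ABUNDANCE_JITTER_SD

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.baseline_abundance = np.asarray(self.baseline_abundance, dtype=float)
        self.aml_multiplier = np.asarray(self.aml_multiplier, dtype=float)
        if (self.sds <= 0).any():
            raise ParameterError("population spreads must be positive")
        if abs(self.baseline_abundance.sum() - 1.0) > 1e-9:
            raise ParameterError("baseline abundances must sum to 1")

    def class_abundance(self, class_label: str) -> np.ndarray:
        """Population abundances for one class, renormalized to 1."""
        a = self.baseline_abundance.copy()
        if class_label == "AML":
            a = a * self.aml_multiplier
        return a / a.sum()

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("means", "sds", "baseline_abundance", "aml_multiplier"):
            d[key] = np.asarray(d[key]).tolist()
        return d

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict())
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationTemplate":
        return cls(**d)

    @classmethod
    def from_json(cls, source: str | Path) -> "PopulationTemplate":
        from .spade import _text_or_file

        return cls.from_dict(json.loads(_text_or_file(source)))


@dataclass
class CohortSpec:
    """Cohort dimensions; defaults are the package's standard test-bench
    cohort (40 samples at roughly 9:1 normal:AML, mirroring a screening
    cohort's class imbalance, 3000-6000 cells per file)."""

    n_normal: int = 32
    n_aml: int = 8
    cells_min: int = 3000
    cells_max: int = 6000
    n_tubes: int = 8
    seed: int = 0
    train_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.n_normal < 1 or self.n_aml < 1:
            raise ParameterError("need at least one sample of each class")
        if not (0 < self.cells_min <= self.cells_max):
            raise ParameterError("invalid cells-per-file range")


def _tube_channel_names(tube: int, n_tubes: int) -> list[str]:
    base = ["FSC", "SSC"]
    if _is_isotype(tube, n_tubes):
        return base + ["IgG1-FL1", "IgG1-FL2", "CD45", "IgG1-FL4", "IgG1-FL5"]
    if _is_unstained(tube, n_tubes):
        return base + [f"NS{k}" for k in range(1, 6)]
    return base + [f"T{tube}M1", f"T{tube}M2", "CD45", f"T{tube}M4", f"T{tube}M5"]


def _is_isotype(tube: int, n_tubes: int) -> bool:
    return n_tubes >= 4 and tube == 1


def _is_unstained(tube: int, n_tubes: int) -> bool:
    return n_tubes >= 4 and tube == n_tubes


def _even_parity_codes(n: int) -> np.ndarray:
    """n binary 4-bit codes with pairwise Hamming distance >= 2 (n <= 8)."""
    codes = [c for c in range(16) if bin(c).count("1") % 2 == 0]
    bits = np.array([[(c >> b) & 1 for b in range(4)] for c in codes], dtype=float)
    return bits[:n]


def make_template(
    n_populations: int = 8,
    n_tubes: int = 8,
    effect_size: float = 1.5,
    seed: int | None = None,
    n_blast: int = 1,
    separation_factor: float = 4.0,
    max_tries: int = 50,
) -> PopulationTemplate:
    """Draw a random population template with guaranteed separation.

    ``effect_size`` is the log abundance shift of the blast-like
    population(s) in AML samples (multiplier ``exp(effect_size)``); 0 gives
    an exact null model.  Population means are redrawn up to ``max_tries``
    times until every informative tube satisfies the pairwise L1 separation
    requirement (``separation_factor`` times the mean total spread); the
    unstained-tube analog is deliberately weakly informative and exempt.
    """
    if n_populations < 2:
        raise ParameterError("need at least two populations")
    if n_populations > 8:
        raise ParameterError("staining patterns support at most 8 populations")
    if effect_size < 0:
        raise ParameterError("effect size must be nonnegative")
    if not 1 <= n_blast < n_populations:
        raise ParameterError("n_blast must be in 1..n_populations-1")
    rng = np.random.default_rng(seed)
    P, T = n_populations, n_tubes

    # shared-channel structure: distinct (SSC, CD45) combos on an even-parity
    # grid, distinct FSC latent means
    grid = np.array(
        [
            (_SHARED_LEVELS[i], _SHARED_LEVELS[j])
            for i in range(4)
            for j in range(4)
            if (i + j) % 2 == 0
        ]
    )

    for _ in range(max_tries):
        combos = grid[rng.choice(len(grid), size=P, replace=False)]
        ssc_mean, cd45_mean = combos[:, 0], combos[:, 1]
        fsc_latent = rng.permutation(np.linspace(-_FSC_LATENT_RANGE, _FSC_LATENT_RANGE, P))

        means = np.empty((T, P, 7))
        sds = np.empty((T, P, 7))
        means[:, :, 0] = _FSC_OFFSET + _FSC_SCALE * fsc_latent
        sds[:, :, 0] = _FSC_SCALE * _FSC_LATENT_SD
        means[:, :, 1] = ssc_mean + rng.uniform(-0.05, 0.05, P)
        sds[:, :, 1] = _MARKER_SD
        cd45 = cd45_mean + rng.uniform(-0.05, 0.05, P)  # shared across tubes

        for t in range(1, T + 1):
            fl = means[t - 1]
            if _is_unstained(t, T):
                fl[:, list(FL_SLOTS)] = _NOISE_MEAN
                sds[t - 1][:, list(FL_SLOTS)] = _NOISE_SD
                continue
            fl[:, CD45_SLOT] = cd45
            sds[t - 1][:, CD45_SLOT] = _MARKER_SD
            if _is_isotype(t, T):
                fl[:, list(MARKER_SLOTS)] = _NOISE_MEAN
                sds[t - 1][:, list(MARKER_SLOTS)] = _NOISE_SD
                continue
            codes = _even_parity_codes(8)
            patterns = codes[rng.choice(len(codes), size=P, replace=False)]
            levels = _NEG_MEAN + (_POS_MEAN - _NEG_MEAN) * patterns
            fl[:, list(MARKER_SLOTS)] = levels + rng.uniform(-0.05, 0.05, (P, 4))
            sds[t - 1][:, list(MARKER_SLOTS)] = _MARKER_SD

        if _separation_ok(means, sds, T, _FSC_OFFSET, _FSC_SCALE, separation_factor):
            break
    else:
        raise SeparationError(
            f"could not draw well-separated populations in {max_tries} tries"
        )

    blast = list(range(n_blast))
    baseline = np.empty(P)
    baseline[blast] = _BLAST_BASELINE
    rest = [p for p in range(P) if p not in blast]
    baseline[rest] = rng.dirichlet(np.full(len(rest), 5.0)) * (
        1.0 - _BLAST_BASELINE * n_blast
    )
    mult = np.ones(P)
    mult[blast] = np.exp(effect_size)

    return PopulationTemplate(
        n_populations=P,
        n_tubes=T,
        channel_names=[_tube_channel_names(t, T) for t in range(1, T + 1)],
        means=means,
        sds=sds,
        baseline_abundance=baseline,
        aml_multiplier=mult,
        blast_populations=blast,
    )


def _separation_ok(
    means: np.ndarray,
    sds: np.ndarray,
    n_tubes: int,
    fsc_offset: float,
    fsc_scale: float,
    factor: float,
) -> bool:
    """Min pairwise L1 separation >= factor x mean spread, per informative
    tube, computed on the analysis scale (FSC mapped back to latent units)."""
    for t in range(1, n_tubes + 1):
        if _is_unstained(t, n_tubes):
            continue  # controls are weakly informative by design
        m = means[t - 1].copy()
        s = sds[t - 1].copy()
        m[:, 0] = (m[:, 0] - fsc_offset) / fsc_scale
        s[:, 0] = s[:, 0] / fsc_scale
        if _is_isotype(t, n_tubes):
            cols = [0, 1, CD45_SLOT]
            m, s = m[:, cols], s[:, cols]
        threshold = factor * s.sum(axis=1).mean()
        if pdist(m, metric="cityblock").min() < threshold:
            return False
    return True


def simulate_sample(
    template: PopulationTemplate,
    class_label: str,
    n_cells: int,
    seed: int | np.random.Generator | None = None,
    sample_id: str = "S0",
) -> list[CellMatrix]:
    """Draw one sample: a list of CellMatrix, one per tube.

    The per-sample abundance jitter is drawn once and shared across tubes
    (the tubes are aliquots of the same specimen); cell draws are independent
    between tubes.  Deterministic given the seed.
    """
    if n_cells < 1:
        raise ParameterError("n_cells must be positive")
    if class_label not in ("normal", "AML"):
        raise ParameterError(f"class label {class_label!r} not in normal/AML")
    rng = np.random.default_rng(seed)
    base = template.class_abundance(class_label)
    logits = np.log(base) + rng.normal(0.0, template.abundance_jitter_sd, base.size)
    p = np.exp(logits - logits.max())
    p /= p.sum()

    out = []
    for t in range(template.n_tubes):
        counts = rng.multinomial(n_cells, p)
        blocks = [
            rng.normal(template.means[t, pop], template.sds[t, pop], (c, 7))
            for pop, c in enumerate(counts)
            if c > 0
        ]
        values = np.concatenate(blocks, axis=0)
        values = values[rng.permutation(n_cells)]
        out.append(
            CellMatrix(sample_id, t + 1, list(template.channel_names[t]), values)
        )
    return out


def simulate_cohort(
    spec: CohortSpec,
    template: PopulationTemplate,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, dict[tuple[str, int], CellMatrix]]:
    """Generate a full cohort with a stratified train/test split.

    Returns the manifest (one row per sample x tube; the ``label`` column
    keeps the generating truth for both splits, the ``split`` column marks
    held-out samples) and the in-memory cells keyed by (sample_id, tube_id).
    If ``out_dir`` is given, per-file CSVs and ``manifest.csv`` are written
    there with paths relative to the manifest.
    """
    if template.n_tubes != spec.n_tubes:
        raise ParameterError(
            f"template has {template.n_tubes} tubes, spec requests {spec.n_tubes}"
        )
    rng = np.random.default_rng(spec.seed)
    n = spec.n_normal + spec.n_aml
    labels = np.array(["normal"] * spec.n_normal + ["AML"] * spec.n_aml)
    labels = labels[rng.permutation(n)]
    sample_ids = [f"sample_{i + 1:03d}" for i in range(n)]

    split = np.empty(n, dtype=object)
    for cls in ("normal", "AML"):
        idx = np.flatnonzero(labels == cls)
        idx = idx[rng.permutation(idx.size)]
        n_train = max(1, int(round(spec.train_fraction * idx.size)))
        n_train = min(n_train, idx.size - 1) if idx.size > 1 else n_train
        split[idx[:n_train]] = "train"
        split[idx[n_train:]] = "test"

    n_cells = rng.integers(spec.cells_min, spec.cells_max + 1, size=n)
    children = np.random.SeedSequence(spec.seed).spawn(n)

    cells: dict[tuple[str, int], CellMatrix] = {}
    rows = []
    out_dir = Path(out_dir) if out_dir is not None else None
    for i, sid in enumerate(sample_ids):
        tubes = simulate_sample(
            template, labels[i], int(n_cells[i]), seed=children[i], sample_id=sid
        )
        for cm in tubes:
            cells[(sid, cm.tube_id)] = cm
            rel = f"{sid}_tube_{cm.tube_id}.csv"
            if out_dir is not None:
                write_tube_csv(cm, out_dir / rel)
            rows.append(
                {
                    "sample_id": sid,
                    "tube_id": cm.tube_id,
                    "path": rel,
                    "label": labels[i],
                    "split": split[i],
                }
            )
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        write_manifest(manifest, out_dir / "manifest.csv")
        template.to_json(out_dir / "template.json")
    return manifest, cells
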