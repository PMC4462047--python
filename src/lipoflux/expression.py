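"""FPKM time-course pattern analysis across the nitrogen-exhaustion switch.

The experimental design this module serves: expression is profiled at six
time points spanning nitrogen exhaustion — three before (A: −12 h,
B: −2 h, E: −30 min, the proliferative "pre" phase) and three after
(K: +1 h, L: +12 h, M: +48 h, the lipogenic "post" phase).  Sample E, the
last point before exhaustion, is the reference for fold changes.

Conventions:

* FPKM values below the detection floor (default 0.05, the smallest
  reliably detected non-zero value) are raised to the floor before any
  log or ratio; this makes fold changes from/to zero well defined.
* Fold changes are signed symmetric ratios: for r = sample/reference,
  the reported fold is max(r, 1/r) with sign + if r ≥ 1, − otherwise.
* A gene is called up- (down-) regulated when the mean floored post-phase
  FPKM is at least ``up_threshold`` times (at most 1/``up_threshold``
  times) the mean floored pre-phase FPKM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from lipoflux.model import ValidationError

__all__ = [
    "ExpressionMatrix",
    "RegulationTable",
    "FoldChangeSpectrum",
    "ConcordanceResult",
    "SampleClustering",
    "floor_and_log",
    "fold_changes",
    "fold_change_spectrum",
    "classify_regulation",
    "concordance",
    "cluster_samples",
    "core_gene_table",
    "DEFAULT_FLOOR",
    "DEFAULT_BIN_EDGES",
]

DEFAULT_FLOOR = 0.05  # FPKM detection limit
DEFAULT_BIN_EDGES = (5.0, 10.0, 100.0, 1000.0)
DIRECTIONS = ("up", "down", "unchanged")

#: The six-sample design: label → (phase, time offset in hours relative to
#: nitrogen exhaustion; negative = before).
STANDARD_SAMPLES: dict[str, tuple[str, float]] = {
    "A": ("pre", -12.0),
    "B": ("pre", -2.0),
    "E": ("pre", -0.5),
    "K": ("post", 1.0),
    "L": ("post", 12.0),
    "M": ("post", 48.0),
}


@dataclass
class ExpressionMatrix:
    """Genes × samples FPKM table with per-sample phase and time metadata."""

    values: pd.DataFrame  # genes (index) × samples (columns), FPKM ≥ 0
    phases: dict[str, str]  # sample label → "pre" | "post"
    times: dict[str, float] = field(default_factory=dict)  # label → hours

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise ValidationError("duplicate sample labels")
        if self.values.index.duplicated().any():
            raise ValidationError("duplicate gene ids")
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("FPKM values must be non-negative")
        for label in self.values.columns:
            phase = self.phases.get(label)
            if phase not in ("pre", "post"):
                raise ValidationError(f"sample {label!r} has no valid phase tag (pre/post)")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def phase_samples(self, phase: str) -> list[str]:
        return [s for s in self.samples if self.phases[s] == phase]

    # --- TSV I/O (first column gene id, header of sample labels; sidecar
    # maps sample → phase and time) ------------------------------------------

    @classmethod
    def from_tsv(cls, fpkm_path: str | Path, phases_path: str | Path) -> "ExpressionMatrix":
        values = pd.read_csv(fpkm_path, sep="\t", index_col=0)
        sidecar = pd.read_csv(phases_path, sep="\t", index_col=0)
        phases = sidecar["phase"].to_dict()
        times = sidecar["time_h"].astype(float).to_dict() if "time_h" in sidecar else {}
        return cls(values=values, phases=phases, times=times)

    def to_tsv(self, fpkm_path: str | Path, phases_path: str | Path) -> None:
        self.values.to_csv(fpkm_path, sep="\t", float_format="%.9g")
        sidecar = pd.DataFrame(
            {
                "phase": [self.phases[s] for s in self.samples],
                "time_h": [self.times.get(s, np.nan) for s in self.samples],
            },
            index=pd.Index(self.samples, name="sample"),
        )
        sidecar.to_csv(phases_path, sep="\t", float_format="%.9g")


@dataclass
class RegulationTable:
    """Gene → regulation direction ("up"/"down"/"unchanged"), with optional
    enzyme labels and pathway tags."""

    directions: dict[str, str]
    enzymes: dict[str, str] = field(default_factory=dict)
    pathways: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, direction in self.directions.items():
            if direction not in DIRECTIONS:
                raise ValidationError(
                    f"gene {gene!r}: direction {direction!r} not in {DIRECTIONS}"
                )

    def __len__(self) -> int:
        return len(self.directions)

    def __getitem__(self, gene: str) -> str:
        return self.directions[gene]

    def genes_with(self, direction: str) -> list[str]:
        return [g for g, d in self.directions.items() if d == direction]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RegulationTable":
        table = pd.read_csv(path, sep="\t", index_col=0)
        return cls(directions=table["direction"].to_dict())

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"direction": pd.Series(self.directions)},
        ).rename_axis("gene").to_csv(path, sep="\t")


@dataclass
class FoldChangeSpectrum:
    """Distribution of differentially expressed genes over fold-change bins.

    Bins are half-open ``[edge_i, edge_{i+1})`` with the last bin
    ``[edge_last, ∞)``; a gene is differentially expressed (DE) when its
    maximum absolute fold over samples reaches the first edge.  When no
    gene is DE the proportions are undefined (None), not an error.
    """

    edges: tuple[float, ...]
    counts: tuple[int, ...]
    n_de: int

    @property
    def proportions(self) -> tuple[float, ...] | None:
        if self.n_de == 0:
            return None
        return tuple(c / self.n_de for c in self.counts)

    @property
    def bin_labels(self) -> tuple[str, ...]:
        labels = [
            f"[{self.edges[i]:g}, {self.edges[i + 1]:g})" for i in range(len(self.edges) - 1)
        ]
        labels.append(f"[{self.edges[-1]:g}, inf)")
        return tuple(labels)


@dataclass
class ConcordanceResult:
    """Directional agreement between two regulation tables on shared genes."""

    fraction: float
    shared: int
    discordant: list[str]

    def __float__(self) -> float:
        return self.fraction


@dataclass
class SampleClustering:
    """Average-linkage tree over samples (distance = 1 − Pearson r)."""

    linkage: np.ndarray  # scipy linkage matrix
    labels: list[str]
    distances: pd.DataFrame  # condensed pairwise distances, square form

    def merge_order(self) -> list[tuple[frozenset[str], frozenset[str], float]]:
        """Clusters merged at each agglomeration step, with heights."""
        clusters: dict[int, frozenset[str]] = {
            i: frozenset([lab]) for i, lab in enumerate(self.labels)
        }
        merges = []
        next_id = len(self.labels)
        for a, b, height, _ in self.linkage:
            left, right = clusters[int(a)], clusters[int(b)]
            merges.append((left, right, float(height)))
            clusters[next_id] = left | right
            next_id += 1
        return merges

    def first_merge(self) -> frozenset[str]:
        left, right, _ = self.merge_order()[0]
        return left | right

    def top_split(self) -> tuple[frozenset[str], frozenset[str]]:
        left, right, _ = self.merge_order()[-1]
        return left, right


# --- operations --------------------------------------------------------------


def _as_frame(matrix) -> pd.DataFrame:
    return matrix.values if isinstance(matrix, ExpressionMatrix) else pd.DataFrame(matrix)


def floor_and_log(matrix, floor: float = DEFAULT_FLOOR) -> pd.DataFrame:
    """Raise values below the detection floor to the floor, then log10.

    ``floor_and_log(0) = log10(0.05) = −1.30103`` under the default floor.
    Idempotent in the sense that flooring the exponentiated output changes
    nothing, and monotone non-decreasing.
    """
    if floor <= 0:
        raise ValidationError(f"floor must be > 0, got {floor}")
    frame = _as_frame(matrix)
    if (frame.to_numpy() < 0).any():
        raise ValidationError("negative FPKM value in input")
    return np.log10(frame.clip(lower=floor))


def fold_changes(
    matrix,
    reference_sample: str,
    floor: float = DEFAULT_FLOOR,
) -> pd.DataFrame:
    """Signed symmetric fold changes of every sample against the reference.

    Both operands are floored, then for r = sample/reference the entry is
    ``sign × max(r, 1/r)`` with sign + when r ≥ 1.  The reference column
    is identically +1.
    """
    if floor <= 0:
        raise ValidationError(f"floor must be > 0, got {floor}")
    frame = _as_frame(matrix)
    if reference_sample not in frame.columns:
        raise ValidationError(f"reference sample {reference_sample!r} not in matrix")
    if (frame.to_numpy() < 0).any():
        raise ValidationError("negative FPKM value in input")
    floored = frame.clip(lower=floor)
    ratio = floored.div(floored[reference_sample], axis=0)
    signed = np.where(ratio.to_numpy() >= 1.0, ratio.to_numpy(), -1.0 / ratio.to_numpy())
    out = pd.DataFrame(signed, index=frame.index, columns=frame.columns)
    out[reference_sample] = 1.0
    return out


def fold_change_spectrum(
    fc_table: pd.DataFrame,
    edges: Sequence[float] = DEFAULT_BIN_EDGES,
    reference_sample: str | None = None,
) -> FoldChangeSpectrum:
    """Bin differentially expressed genes by their maximum absolute fold.

    A gene is DE when its max |fold| across (non-reference) samples is at
    least ``edges[0]``; each DE gene lands in exactly one half-open bin.
    """
    edges = tuple(float(e) for e in edges)
    if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValidationError(f"edges must be strictly increasing with ≥ 2 entries: {edges}")
    frame = fc_table.drop(columns=[reference_sample]) if reference_sample else fc_table
    max_fold = frame.abs().max(axis=1)
    de = max_fold[max_fold >= edges[0]]
    counts = []
    for i in range(len(edges)):
        upper = edges[i + 1] if i + 1 < len(edges) else np.inf
        counts.append(int(((de >= edges[i]) & (de < upper)).sum()))
    return FoldChangeSpectrum(edges=edges, counts=tuple(counts), n_de=int(len(de)))


def classify_regulation(
    matrix: ExpressionMatrix,
    up_threshold: float = 2.0,
    floor: float = DEFAULT_FLOOR,
) -> RegulationTable:
    """Call up/down/unchanged per gene from phase-mean ratios.

    ρ = mean(floored post FPKM) / mean(floored pre FPKM); up if
    ρ ≥ up_threshold, down if ρ ≤ 1/up_threshold, else unchanged.
    """
    if up_threshold <= 1:
        raise ValidationError(f"up_threshold must be > 1, got {up_threshold}")
    pre = matrix.phase_samples("pre")
    post = matrix.phase_samples("post")
    if not pre or not post:
        raise ValidationError("classification needs at least one pre and one post sample")
    floored = matrix.values.clip(lower=floor)
    rho = floored[post].mean(axis=1) / floored[pre].mean(axis=1)
    directions = {}
    for gene, r in rho.items():
        if r >= up_threshold:
            directions[gene] = "up"
        elif r <= 1.0 / up_threshold:
            directions[gene] = "down"
        else:
            directions[gene] = "unchanged"
    return RegulationTable(directions=directions)


def concordance(a: RegulationTable, b: RegulationTable) -> ConcordanceResult:
    """Fraction of shared genes with identical direction labels.

    Symmetric; equals 1 iff the shared labels are identical.  Also lists
    the discordant genes (e.g. a single MDH flip over a 23-gene core gives
    22/23 ≈ 0.9565).
    """
    shared = sorted(set(a.directions) & set(b.directions))
    if not shared:
        raise ValidationError("regulation tables share no genes")
    discordant = [g for g in shared if a[g] != b[g]]
    return ConcordanceResult(
        fraction=(len(shared) - len(discordant)) / len(shared),
        shared=len(shared),
        discordant=discordant,
    )


def cluster_samples(matrix: ExpressionMatrix, floor: float = DEFAULT_FLOOR) -> SampleClustering:
    """Agglomerative clustering of samples on floored log10 values.

    Distance = 1 − Pearson correlation between sample columns, average
    linkage; leaf order is deterministic.  A constant sample vector has no
    defined correlation and is reported by name.
    """
    if len(matrix.samples) < 2:
        raise ValidationError("clustering needs at least 2 samples")
    logged = floor_and_log(matrix, floor=floor)
    data = logged.to_numpy().T  # samples × genes
    stds = data.std(axis=1)
    for label, std in zip(matrix.samples, stds):
        if std == 0:
            raise ValidationError(
                f"sample {label!r} is constant; Pearson correlation is undefined"
            )
    condensed = pdist(data, metric="correlation")  # 1 − r
    linkage = hierarchy.linkage(condensed, method="average")
    square = np.zeros((len(matrix.samples),) * 2)
    iu = np.triu_indices(len(matrix.samples), k=1)
    square[iu] = condensed
    square += square.T
    distances = pd.DataFrame(square, index=matrix.samples, columns=matrix.samples)
    return SampleClustering(linkage=linkage, labels=matrix.samples, distances=distances)


# --- the 23-gene lipogenesis regulation core ---------------------------------

# Direction calls across the nitrogen-exhaustion switch for the core
# carbon-flux / NADPH enzymes.  HK is counted once (EC 2.7.1.1 and
# EC 2.7.1.2 grouped under a single hexokinase entry), giving 23 genes:
# 14 up, 9 down.
_CORE_GENES: tuple[tuple[str, str, str, str], ...] = (
    # gene, direction, enzyme, pathway
    ("PK", "up", "pyruvate kinase (EC 2.7.1.40)", "glycolysis"),
    ("PCK", "up", "phosphoenolpyruvate carboxykinase (EC 4.1.1.32/49)", "glycolysis"),
    ("HK", "down", "hexokinase (EC 2.7.1.1/2.7.1.2)", "glycolysis"),
    ("ALDO", "down", "fructose-1,6-bisphosphate aldolase (EC 4.1.2.13)", "glycolysis"),
    ("GAPDH", "down", "glyceraldehyde-3-phosphate dehydrogenase (EC 1.2.1.12)", "glycolysis"),
    ("ENO", "down", "phosphopyruvate hydratase (EC 4.2.1.11)", "glycolysis"),
    ("ACO", "down", "aconitase (EC 4.2.1.3)", "TCA cycle"),
    ("IDH", "down", "isocitrate dehydrogenase (EC 1.1.1.42)", "TCA cycle"),
    ("PDH", "up", "pyruvate dehydrogenase (EC 1.2.4.1)", "TCA cycle"),
    ("OGDH", "up", "2-oxoglutarate dehydrogenase (EC 1.2.4.2)", "TCA cycle"),
    ("SUCLG", "up", "succinyl-CoA synthetase (EC 6.2.1.4)", "TCA cycle"),
    ("MDH", "down", "malate dehydrogenase (EC 1.1.1.37)", "TCA cycle"),
    ("ACLY", "up", "ATP-citrate lyase (EC 2.3.3.8)", "fatty acid synthesis"),
    ("ACS", "up", "acetyl-CoA synthetase (EC 6.2.1.1)", "fatty acid synthesis"),
    ("ALDH", "up", "aldehyde dehydrogenase (EC 1.2.1.3)", "glycerolipid synthesis"),
    ("ADH", "up", "alcohol dehydrogenase (EC 1.1.1.2)", "glycerolipid synthesis"),
    ("GPAT", "up", "glycerol-3-phosphate acyltransferase (EC 2.3.1.15)", "glycerolipid synthesis"),
    ("DGAT", "up", "diacylglycerol O-acyltransferase (EC 2.3.1.20)", "glycerolipid synthesis"),
    ("ACSL", "up", "acyl-CoA synthetase (EC 6.2.1.3)", "glycerolipid synthesis"),
    ("CRAT", "down", "carnitine O-acetyltransferase (EC 2.3.1.7)", "beta-oxidation"),
    ("LIP", "down", "triacylglycerol lipase (EC 3.1.1.3)", "glycerolipid synthesis"),
    ("G6PD", "up", "glucose-6-phosphate dehydrogenase (EC 1.1.1.49)", "pentose phosphate pathway"),
    ("PGD", "up", "6-phosphogluconate dehydrogenase (EC 1.1.1.44)", "pentose phosphate pathway"),
)


def core_gene_table() -> RegulationTable:
    """The bundled 23-gene lipogenesis regulation core (14 up, 9 down).

    These are the coordinated direction calls for central carbon flux,
    precursor supply, glycerolipid assembly and PPP NADPH production
    across the nitrogen-exhaustion switch in an oleaginous fungus.
    """
    return RegulationTable(
        directions={g: d for g, d, _, _ in _CORE_GENES},
        enzymes={g: e for g, _, e, _ in _CORE_GENES},
        pathways={g: p for g, _, _, p in _CORE_GENES},
    )
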