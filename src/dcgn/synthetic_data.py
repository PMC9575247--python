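"""Synthetic gene-expression generator with known class structure.

Each class draws from a Gaussian centred on its own mean vector: a sparse,
class-specific block of informative genes is shifted by ``effect_size``
(in noise-sd units) and everything else is centred at zero, mimicking the
continuous, high-dimensional, severely imbalanced matrices seen in
subtype-labelled tumour expression studies.  Informative-gene blocks are
disjoint across classes, so ground truth is unambiguous and written into
the dataset's metadata.  A log-normal option gives RNA-seq-like positive
values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_config import ExpressionDataset


@dataclass
class SimulationSpec:
    """Shape and signal parameters of one simulated dataset."""

    n_classes: int = 3
    class_counts: tuple[int, ...] = (40, 40, 40)
    n_genes: int = 256
    n_informative: int = 24
    effect_size: float = 3.0
    noise_sd: float = 1.0
    within_class_corr: float = 0.0
    lognormal: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.class_counts = tuple(int(c) for c in self.class_counts)
        problems = []
        if self.n_classes < 2:
            problems.append(f"n_classes {self.n_classes} < 2")
        if len(self.class_counts) != self.n_classes:
            problems.append(
                f"{len(self.class_counts)} class counts for {self.n_classes} classes"
            )
        if any(c < 2 for c in self.class_counts):
            problems.append("every class needs >= 2 samples")
        if self.n_informative > self.n_genes:
            problems.append(
                f"n_informative {self.n_informative} > n_genes {self.n_genes}"
            )
        if self.effect_size < 0:
            problems.append("effect_size must be >= 0")
        if not (0.0 <= self.within_class_corr < 1.0):
            problems.append("within_class_corr must lie in [0, 1)")
        if self.noise_sd <= 0:
            problems.append("noise_sd must be > 0")
        if problems:
            raise ValueError("invalid simulation spec: " + "; ".join(problems))


def simulate_dataset(spec: SimulationSpec) -> ExpressionDataset:
    """Draw one dataset; deterministic under ``spec.seed``.

    Class ``c`` gets a disjoint block of ``n_informative // n_classes``
    informative genes whose mean is shifted by ``effect_size * noise_sd``;
    all other genes are pure noise.  The informative gene lists and class
    mean vectors are stored in the returned dataset's ``metadata`` under
    ``"ground_truth"``.
    """
    rng = np.random.default_rng(spec.seed)
    n = sum(spec.class_counts)
    block = spec.n_informative // spec.n_classes
    labels = np.repeat(np.arange(spec.n_classes), spec.class_counts)

    means = np.zeros((spec.n_classes, spec.n_genes))
    informative: dict[int, list[int]] = {}
    for c in range(spec.n_classes):
        genes = list(range(c * block, (c + 1) * block))
        informative[c] = genes
        means[c, genes] = spec.effect_size * spec.noise_sd

    values = rng.normal(0.0, spec.noise_sd, size=(n, spec.n_genes))
    if spec.within_class_corr > 0:
        # equicorrelation across informative genes via a shared per-sample factor
        rho = spec.within_class_corr
        shared = rng.normal(0.0, spec.noise_sd, size=(n, 1))
        info_cols = np.arange(spec.n_classes * block)
        values[:, info_cols] = (
            np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * values[:, info_cols]
        )
    values += means[labels]
    if spec.lognormal:
        values = np.exp(values)

    ground_truth = {
        "informative_genes": {str(c): g for c, g in informative.items()},
        "class_means": means.tolist(),
    }
    return ExpressionDataset(
        sample_ids=[f"s{i:05d}" for i in range(n)],
        gene_ids=[f"g{j:05d}" for j in range(spec.n_genes)],
        values=values,
        labels=labels,
        label_names=[f"class_{c}" for c in range(spec.n_classes)],
        metadata={"ground_truth": ground_truth},
    )


#: class counts used by the presets; the breast-cancer-like preset keeps the
#: hallmark imbalance of subtype-labelled cohorts (721 in its third class,
#: 202 in its fifth and only 150 in its sixth), totalling 2133 samples.
_BRCA_COUNTS = (480, 330, 721, 250, 202, 150)

_BLCA_TOTALS = {"MDA": (3, 1010), "TCGA": (5, 761), "CIT-Curie": (7, 909), "Lund": (10, 1185)}


def _imbalanced_counts(n_classes: int, total: int) -> tuple[int, ...]:
    """Deterministic geometric-ish imbalance summing exactly to ``total``."""
    raw = np.geomspace(1.0, 4.0, n_classes)
    counts = np.maximum((raw / raw.sum() * total).astype(int), 2)
    counts[-1] += total - counts.sum()
    return tuple(int(c) for c in counts)


def preset(name: str, seed: int = 0) -> SimulationSpec:
    """Named simulation presets.

    ``tiny``: 3 balanced classes x 40 samples, 256 genes — fast tests.
    ``brca_like``: 6 classes, 2133 samples with the 150/202/721 imbalance,
    20,000 genes.  ``blca_like:<system>`` with system one of MDA, TCGA,
    CIT-Curie, Lund: class counts of the four bladder-cancer labeling
    systems (3/5/7/10 classes).
    """
    if name == "tiny":
        return SimulationSpec(
            n_classes=3,
            class_counts=(40, 40, 40),
            n_genes=256,
            n_informative=24,
            effect_size=3.0,
            noise_sd=1.0,
            seed=seed,
        )
    if name == "brca_like":
        return SimulationSpec(
            n_classes=6,
            class_counts=_BRCA_COUNTS,
            n_genes=20_000,
            n_informative=300,
            effect_size=1.5,
            noise_sd=1.0,
            seed=seed,
        )
    if name.startswith("blca_like"):
        system = name.split(":", 1)[1] if ":" in name else "TCGA"
        if system not in _BLCA_TOTALS:
            raise ValueError(
                f"unknown labeling system {system!r}; choose from "
                f"{sorted(_BLCA_TOTALS)}"
            )
        n_classes, total = _BLCA_TOTALS[system]
        return SimulationSpec(
            n_classes=n_classes,
            class_counts=_imbalanced_counts(n_classes, total),
            n_genes=20_000,
            n_informative=50 * n_classes,
            effect_size=1.5,
            noise_sd=1.0,
            seed=seed,
        )
    raise ValueError(f"unknown preset {name!r}")
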