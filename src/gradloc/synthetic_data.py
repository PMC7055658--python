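"""Two-replicate TMT-style fractionation datasets with known ground truth.

The generator emulates the statistical structure the analysis assumes: each
protein has a class-specific expected logFC profile over the ten gradient
fractions, a log-normal baseline abundance (the total-membrane channel),
multiplicative (log-Gaussian) measurement noise, and per-replicate-per-channel
batch offsets. Class sizes default to the benchmark composition of a typical
E. coli membrane preparation: IM 495, OM 98, soluble 632, peripheral-IM
(IM-cyto) 316 split roughly 1:2 membrane:soluble, plus small transenvelope
and dual-localized contingents.

Special classes exercise the pipeline's edge logic: transenvelope proteins
(TonB/TamB-like) are annotated IM but fractionate flat and should surface as
soluble calls and annotation mismatches; dual-localized proteins mix the IM
and OM templates; IM-cyto proteins are annotated ambiguously so the pipeline
must resolve them; a fraction of soluble proteins carries a weak membrane
tail (vesicle-surface contamination).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .io_formats import CHANNELS, FRACTIONS, AnnotationTable, SignalMatrix

log = logging.getLogger(__name__)

#: Generator class labels.
CLASSES = (
    "IM",
    "OM",
    "soluble",
    "IM-cyto-membrane",
    "IM-cyto-soluble",
    "transenvelope",
    "dual",
)

#: Localization the assay is expected to report for each class (dual is drawn
#: per protein from its mixing weight).
EXPECTED_LOCALIZATION = {
    "IM": "IM",
    "OM": "OM",
    "soluble": "soluble",
    "IM-cyto-membrane": "IM",
    "IM-cyto-soluble": "soluble",
    "transenvelope": "soluble",
}


@dataclass
class GeneratorConfig:
    """Study conditions for one simulated dataset.

    ``delta`` is the class enrichment amplitude in log2 units (an IM protein
    is delta/2 above baseline in the low-density fractions and delta/2 below
    in the high-density ones, so its template sucrose ratio is -delta).
    ``sigma`` is per-cell Gaussian noise on the log2 scale. Batch offsets are
    drawn once per replicate x channel from U(-batch_offset_range, +range).
    """

    seed: int
    n_im: int = 495
    n_om: int = 98
    n_soluble: int = 632
    n_imcyto_membrane: int = 105
    n_imcyto_soluble: int = 211
    n_transenvelope: int = 10
    n_dual: int = 12
    delta: float = 2.0
    sigma: float = 0.4
    batch_offset_range: float = 0.3
    abundance_log2_mean: float = 17.0
    abundance_log2_sd: float = 1.5
    contamination_rate: float = 0.1
    contamination_strength: float = 0.3
    imcyto_attenuation: float = 0.7

    def __post_init__(self) -> None:
        counts = self.class_counts()
        if any(n < 0 for n in counts.values()):
            raise ConfigurationError("class counts must be >= 0")
        if sum(counts.values()) == 0:
            raise ConfigurationError("cannot simulate a dataset with zero proteins")
        if self.sigma < 0:
            raise ConfigurationError("noise sigma must be >= 0")
        if not 0 <= self.contamination_rate <= 1:
            raise ConfigurationError("contamination_rate must be in [0, 1]")

    def class_counts(self) -> dict[str, int]:
        return {
            "IM": self.n_im,
            "OM": self.n_om,
            "soluble": self.n_soluble,
            "IM-cyto-membrane": self.n_imcyto_membrane,
            "IM-cyto-soluble": self.n_imcyto_soluble,
            "transenvelope": self.n_transenvelope,
            "dual": self.n_dual,
        }


@dataclass
class SimulatedData:
    """A generated two-replicate dataset plus its ground truth."""

    config: GeneratorConfig
    replicates: tuple[SignalMatrix, SignalMatrix]
    annotation: AnnotationTable
    truth: pd.DataFrame  # index protein_id: true_class, expected_localization, ...
    templates: pd.DataFrame  # per protein 10-vector expected logfc
    batch_offsets: np.ndarray  # 2 x 11 (replicate x channel) log2 shifts


def make_templates(delta: float = 2.0, imcyto_attenuation: float = 0.7) -> dict[str, np.ndarray]:
    """Class -> expected logFC 10-vector over f02..f11.

    The IM template sits at +delta/2 in the low-density fractions, ramps down
    monotonically through f05-f07, and sits at -delta/2 from f08 on; the OM
    template is its mirror image; soluble and transenvelope proteins are flat.
    The membrane-resolved IM-cyto template is the IM template attenuated
    (peripheral rather than integral association).
    """
    half = delta / 2.0
    ramp = np.linspace(half, -half, 5)[1:-1]  # f05, f06, f07
    im = np.concatenate([[half] * 3, ramp, [-half] * 4])
    templates = {
        "IM": im,
        "OM": -im,
        "soluble": np.zeros(10),
        "transenvelope": np.zeros(10),
        "IM-cyto-membrane": imcyto_attenuation * im,
        "IM-cyto-soluble": np.zeros(10),
    }
    return {k: v.astype(float) for k, v in templates.items()}


def template_ratio(template: np.ndarray) -> float:
    """Sucrose gradient ratio of a template profile."""
    return float(template[6:9].mean() - template[0:3].mean())


def _annotate(classes: np.ndarray, rng: np.random.Generator) -> pd.Series:
    """Draw STEPdb-style categories consistent with the generating classes."""
    cats = np.empty(len(classes), dtype=object)
    for i, cls in enumerate(classes):
        if cls == "IM":
            cats[i] = rng.choice(["IM-integral", "IM-peri", "IMLP"], p=[0.65, 0.25, 0.10])
        elif cls == "OM":
            cats[i] = rng.choice(["OMP", "OMLP"], p=[0.7, 0.3])
        elif cls == "soluble":
            cats[i] = rng.choice(["cytoplasmic", "periplasmic"], p=[0.75, 0.25])
        elif cls in ("IM-cyto-membrane", "IM-cyto-soluble"):
            cats[i] = "IM-cyto"
        elif cls == "transenvelope":
            cats[i] = "IM-integral"  # annotated by their anchor membrane
        elif cls == "dual":
            cats[i] = "cytoplasmic"  # dual cytoplasm/membrane moonlighters
    return pd.Series(cats)


def simulate_dataset(cfg: GeneratorConfig) -> SimulatedData:
    """Generate two replicate signal matrices, annotations and ground truth.

    Per protein: total channel = baseline abundance (log-normal); fraction
    channels = abundance x 2^(template + noise + batch offset). Deterministic
    given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    counts = cfg.class_counts()
    classes = np.concatenate([[cls] * n for cls, n in counts.items() if n > 0])
    n = len(classes)
    rng.shuffle(classes)
    ids = pd.Index([f"SYN{i:04d}" for i in range(1, n + 1)], name="protein_id")

    base_templates = make_templates(cfg.delta, cfg.imcyto_attenuation)
    templates = np.zeros((n, 10))
    alpha = np.full(n, np.nan)
    contaminated = np.zeros(n, dtype=bool)
    expected = np.empty(n, dtype=object)
    for i, cls in enumerate(classes):
        if cls == "dual":
            a = rng.uniform(0.3, 0.7)
            alpha[i] = a
            templates[i] = a * base_templates["IM"] + (1 - a) * base_templates["OM"]
        else:
            templates[i] = base_templates[cls]
        if cls == "soluble" and rng.random() < cfg.contamination_rate:
            contaminated[i] = True
            tail = rng.choice(["IM", "OM"])
            templates[i] = templates[i] + cfg.contamination_strength * base_templates[tail]
        if cls == "dual":
            r = template_ratio(templates[i])
            expected[i] = "IM" if r <= -cfg.delta / 2 else "OM" if r >= cfg.delta / 2 else "soluble"
        else:
            expected[i] = EXPECTED_LOCALIZATION[cls]

    abundance_log2 = rng.normal(cfg.abundance_log2_mean, cfg.abundance_log2_sd, size=n)
    batch_offsets = rng.uniform(
        -cfg.batch_offset_range, cfg.batch_offset_range, size=(2, len(CHANNELS))
    )
    if cfg.batch_offset_range == 0:
        batch_offsets = np.zeros((2, len(CHANNELS)))

    peptides = rng.poisson(6.0, size=n) + 1
    low_evidence = rng.random(n) < 0.02
    peptides[low_evidence] = 1
    peptide_series = pd.Series(peptides, index=ids, name="unique_peptides")

    reps = []
    for r in range(2):
        noise_fracs = rng.normal(0.0, cfg.sigma, size=(n, 10)) if cfg.sigma > 0 else np.zeros((n, 10))
        log2_fracs = (
            abundance_log2[:, None] + templates + noise_fracs + batch_offsets[r, :10][None, :]
        )
        # the total-membrane reference is the (noise-free) baseline abundance,
        # subject only to its channel's batch offset
        log2_total = abundance_log2 + batch_offsets[r, 10]
        values = pd.DataFrame(
            np.column_stack([np.power(2.0, log2_fracs), np.power(2.0, log2_total)]),
            index=ids,
            columns=list(CHANNELS),
        )
        reps.append(
            SignalMatrix(
                replicate_id=f"rep{r+1}",
                values=values,
                unique_peptides=peptide_series.copy(),
            )
        )

    annotation = AnnotationTable(categories=_annotate(classes, rng).set_axis(ids))
    truth = pd.DataFrame(
        {
            "true_class": classes,
            "expected_localization": expected,
            "abundance_log2": abundance_log2,
            "contaminated": contaminated,
            "dual_alpha": alpha,
            "discordant": np.zeros(n, dtype=bool),
        },
        index=ids,
    )
    return SimulatedData(
        config=cfg,
        replicates=(reps[0], reps[1]),
        annotation=annotation,
        truth=truth,
        templates=pd.DataFrame(templates, index=ids, columns=list(FRACTIONS)),
        batch_offsets=batch_offsets,
    )


def inject_replicate_discordance(
    data: SimulatedData, fraction: float, seed: int
) -> tuple[SimulatedData, list[str]]:
    """Replace replicate 2's profile with a different class's template for a subset.

    Targets are drawn from the core IM/OM/soluble classes; each selected
    protein's replicate-2 fractions are regenerated from a template whose
    expected localization differs from the protein's own, so the replicate
    consistency filter should catch them. Returns the modified dataset and the
    injected protein list.
    """
    if not 0 <= fraction <= 1:
        raise ConfigurationError("discordance fraction must be in [0, 1]")
    if fraction == 0:
        return data, []
    rng = np.random.default_rng(seed)
    cfg = data.config
    core = data.truth.index[data.truth["true_class"].isin(["IM", "OM", "soluble"])]
    n_pick = int(round(fraction * len(core)))
    picked = list(rng.choice(core.to_numpy(), size=n_pick, replace=False))
    base_templates = make_templates(cfg.delta, cfg.imcyto_attenuation)
    swap = {"IM": ["OM", "soluble"], "OM": ["IM", "soluble"], "soluble": ["IM", "OM"]}

    rep2 = data.replicates[1].copy()
    truth = data.truth.copy()
    for pid in picked:
        cls = truth.at[pid, "true_class"]
        new_cls = rng.choice(swap[cls])
        template = base_templates[new_cls]
        ab = truth.at[pid, "abundance_log2"]
        noise = rng.normal(0.0, cfg.sigma, size=10) if cfg.sigma > 0 else np.zeros(10)
        log2_fracs = ab + template + noise + data.batch_offsets[1, :10]
        log2_total = ab + data.batch_offsets[1, 10]
        rep2.values.loc[pid, list(FRACTIONS)] = np.power(2.0, log2_fracs)
        rep2.values.loc[pid, "total"] = np.power(2.0, log2_total)
        truth.at[pid, "discordant"] = True
    return (
        replace(data, replicates=(data.replicates[0], rep2), truth=truth),
        picked,
    )


def write_dataset(data: SimulatedData, out_dir: str) -> dict[str, str]:
    """Write the dataset's signal, annotation and truth tables as TSVs."""
    import os

    from .io_formats import write_annotation, write_signal_matrix

    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for m in data.replicates:
        path = os.path.join(out_dir, f"signals_{m.replicate_id}.tsv")
        write_signal_matrix(m, path)
        paths[m.replicate_id] = path
    ann_path = os.path.join(out_dir, "annotation.tsv")
    write_annotation(data.annotation, ann_path)
    paths["annotation"] = ann_path
    truth_path = os.path.join(out_dir, "truth.tsv")
    data.truth.to_csv(truth_path, sep="\t")
    paths["truth"] = truth_path
    return paths
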