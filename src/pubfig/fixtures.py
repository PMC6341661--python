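"""Deterministic example-data generators.

Every chart type has a generator here, so the full gallery — and the
documentation — can be rebuilt from a seed with no bundled data files.  The
centrepiece is a synthetic tumour-cohort mutation dataset (genes × patients
with SNV and CNA category matrices, per-SNV base-change classes and clinical
covariates) whose derived summaries are always recomputed from the matrices,
never sampled, so the multi-panel cohort figure is internally consistent by
construction.

What the synthetic cohort emulates: independent per-cell mutation events at
fixed SNV/CNA rates with realistic category frequencies (missense SNVs and
C>T transitions most common, MSS more common than MSI).  What it does not:
mutual exclusivity between driver genes, patient-level mutation-burden
heterogeneity, or correlation between clinical covariates and genotype.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .charts import (
    AxisSpec,
    ChartSpec,
    CovariateBar,
    DotmapData,
    LegendSpec,
    Panel,
    create_chart,
    create_legend,
)
from .multiplot import ComposedFigure, MultiplotLayout, compose
from .palettes import force_colour_scheme
from .theme import Theme

__all__ = [
    "DEFAULT_SEED",
    "MutationDataset",
    "make_mutation_dataset",
    "summarize_mutations",
    "make_fig1_datasets",
    "fig1_gallery",
    "cohort_figure",
    "write_fixture_files",
]

#: Seed used throughout the documentation gallery.
DEFAULT_SEED = 42

_SNV_TYPES = ("missense", "nonsense", "frameshift", "splice", "silent")
_SNV_WEIGHTS = (0.50, 0.15, 0.15, 0.10, 0.10)
_CNA_TYPES = ("gain", "loss")
_CNA_WEIGHTS = (0.5, 0.5)
#: The six pyrimidine-context substitution classes of somatic SNVs.
BASE_CHANGES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASE_WEIGHTS = (0.10, 0.10, 0.45, 0.10, 0.15, 0.10)


@dataclass
class MutationDataset:
    """A synthetic cohort: mutation matrices, clinical covariates, summaries.

    ``snv`` and ``cna`` are genes × patients matrices of nullable category
    codes; ``basechange`` assigns each SNV its substitution class.
    ``derived`` holds summaries recomputed from the matrices:
    ``per_gene_pct`` (percentage of patients with an SNV or CNA per gene),
    ``per_patient_counts`` (SNV and CNA counts per patient) and
    ``basechange_props`` (per-patient proportions of SNVs by class, as a
    fraction of that patient's total mutation count).
    """

    snv: pd.DataFrame
    cna: pd.DataFrame
    basechange: pd.DataFrame
    clinical: pd.DataFrame
    derived: dict

    @property
    def genes(self) -> list[str]:
        return list(self.snv.index)

    @property
    def patients(self) -> list[str]:
        return list(self.snv.columns)


def summarize_mutations(
    snv: pd.DataFrame, cna: pd.DataFrame, basechange: pd.DataFrame
) -> dict:
    """Recompute the cohort summaries from the mutation matrices.

    Pure recount — no sampling — so the summaries always agree with the
    matrices they were computed from.
    """
    snv_mask = snv.notna()
    cna_mask = cna.notna()
    n_patients = snv.shape[1]
    per_gene_pct = 100.0 * (snv_mask | cna_mask).sum(axis=1) / n_patients
    per_patient = pd.DataFrame(
        {"snv": snv_mask.sum(axis=0), "cna": cna_mask.sum(axis=0)}
    )
    total = per_patient["snv"] + per_patient["cna"]
    props = pd.DataFrame(
        0.0, index=snv.columns, columns=list(BASE_CHANGES)
    )
    for patient in snv.columns:
        if total[patient] == 0:
            continue
        classes = basechange.loc[snv_mask[patient], patient]
        counts = classes.value_counts()
        for cls, cnt in counts.items():
            props.loc[patient, cls] = cnt / total[patient]
    return {
        "per_gene_pct": per_gene_pct,
        "per_patient_counts": per_patient,
        "basechange_props": props,
    }


def make_mutation_dataset(
    n_genes: int = 20,
    n_patients: int = 40,
    p_snv: float = 0.1,
    p_cna: float = 0.05,
    seed: int = DEFAULT_SEED,
) -> MutationDataset:
    """Draw a synthetic cohort mutation dataset.

    Each gene × patient cell independently carries an SNV with probability
    ``p_snv`` and a CNA with probability ``p_cna`` (a cell may carry both).
    SNV types, CNA types, base-change classes and clinical categories are
    drawn from the module-level categorical distributions.
    """
    if not (0 <= p_snv <= 1 and 0 <= p_cna <= 1):
        raise ValueError(f"rates must lie in [0, 1]; got p_snv={p_snv}, p_cna={p_cna}")
    if n_genes < 1 or n_patients < 1:
        raise ValueError("n_genes and n_patients must be >= 1")
    rng = np.random.default_rng(seed)
    genes = [f"GENE{i + 1:02d}" for i in range(n_genes)]
    patients = [f"P{i + 1:03d}" for i in range(n_patients)]
    shape = (n_genes, n_patients)

    snv_hit = rng.random(shape) < p_snv
    cna_hit = rng.random(shape) < p_cna
    snv_types = rng.choice(_SNV_TYPES, size=shape, p=_SNV_WEIGHTS)
    cna_types = rng.choice(_CNA_TYPES, size=shape, p=_CNA_WEIGHTS)
    base_cls = rng.choice(BASE_CHANGES, size=shape, p=_BASE_WEIGHTS)

    snv = pd.DataFrame(
        np.where(snv_hit, snv_types, None), index=genes, columns=patients
    )
    cna = pd.DataFrame(
        np.where(cna_hit, cna_types, None), index=genes, columns=patients
    )
    basechange = pd.DataFrame(
        np.where(snv_hit, base_cls, None), index=genes, columns=patients
    )
    clinical = pd.DataFrame(
        {
            "sex": rng.choice(["male", "female"], size=n_patients),
            "stage": rng.choice(["I", "II", "III", "IV"], size=n_patients,
                                p=[0.2, 0.3, 0.3, 0.2]),
            "msi_status": rng.choice(["MSI", "MSS"], size=n_patients, p=[0.3, 0.7]),
        },
        index=patients,
    )
    return MutationDataset(
        snv=snv,
        cna=cna,
        basechange=basechange,
        clinical=clinical,
        derived=summarize_mutations(snv, cna, basechange),
    )


# ---------------------------------------------------------------------------
# one dataset per chart type
# ---------------------------------------------------------------------------


def make_fig1_datasets(seed: int = DEFAULT_SEED) -> dict:
    """One deterministic example dataset per chart type."""
    rng = np.random.default_rng(seed)
    out: dict = {}

    groups = np.repeat(["control", "treated", "resistant"], 40)
    shifts = {"control": 0.0, "treated": 1.2, "resistant": 2.1}
    values = rng.normal(size=120) + np.array([shifts[g] for g in groups])
    grouped = pd.DataFrame({"value": values, "group": groups})
    for name in ("density", "boxplot", "violin", "stripplot"):
        out[name] = grouped.copy()

    cats = [f"gene{i}" for i in range(1, 9)]
    centre = rng.normal(0, 1, size=8)
    half = rng.uniform(0.3, 1.0, size=8)
    out["segplot"] = pd.DataFrame(
        {"category": cats, "centre": centre, "lo": centre - half, "hi": centre + half}
    )

    out["barplot"] = pd.DataFrame(
        {"category": list("ABCDEF"), "value": rng.integers(3, 25, size=6)}
    )

    x = rng.normal(size=200)
    out["scatterplot"] = pd.DataFrame(
        {"x": x, "y": 0.8 * x + rng.normal(scale=0.6, size=200)}
    )

    out["histogram"] = pd.DataFrame({"value": rng.normal(size=200)})
    out["qq_fit"] = pd.DataFrame({"value": rng.normal(loc=0.2, size=80)})

    a = rng.normal(size=100)
    b = rng.normal(loc=0.4, scale=1.3, size=60)
    out["qq_comparison"] = pd.DataFrame(
        {
            "a": a,
            "b": np.concatenate([b, np.full(40, np.nan)]),
        }
    )

    lengths = {"1": 1200, "2": 1000, "3": 800}
    chroms, positions = [], []
    for c, L in lengths.items():
        pos = np.sort(rng.choice(np.arange(1, L + 1), size=100, replace=False))
        chroms += [c] * len(pos)
        positions += list(pos)
    p_values = rng.uniform(1e-4, 1.0, size=len(chroms))
    hits = rng.choice(len(p_values), size=6, replace=False)
    p_values[hits] = 10.0 ** rng.uniform(-9, -5, size=6)
    out["manhattan"] = pd.DataFrame(
        {"chromosome": chroms, "position": positions, "p_value": p_values}
    )

    xg = np.linspace(0, 10, 60)
    out["polygonplot"] = pd.DataFrame(
        {
            "x": xg,
            "clone_a": np.exp(-((xg - 3) ** 2) / 4) * 5,
            "clone_b": np.exp(-((xg - 6.5) ** 2) / 6) * 3.5,
        }
    )

    matrix = rng.normal(size=(12, 10)).cumsum(axis=1)
    out["heatmap"] = pd.DataFrame(
        matrix,
        index=[f"gene{i}" for i in range(1, 13)],
        columns=[f"s{i}" for i in range(1, 11)],
    )

    cohort = make_mutation_dataset(8, 12, p_snv=0.18, p_cna=0.10, seed=seed)
    out["dotmap"] = _dotmap_from_cohort(cohort)

    centres = rng.normal(size=(3, 2)) * 2
    pts = np.vstack(
        [rng.normal(loc=c, scale=0.6, size=(170, 2)) for c in centres]
    )
    out["hexbinplot"] = pd.DataFrame(pts, columns=["x", "y"])
    return out


def _dotmap_from_cohort(ds: MutationDataset) -> DotmapData:
    snv_map = {
        lab: col.to_hex()
        for lab, col in zip(
            force_colour_scheme("mutation.types").labels,
            force_colour_scheme("mutation.types").colours,
        )
    }
    cna_pal = force_colour_scheme("cna.types")
    cna_map = {lab: col.to_hex() for lab, col in zip(cna_pal.labels, cna_pal.colours)}
    return DotmapData.make(
        cell_categories=ds.snv,
        dot_categories=ds.cna,
        cell_colour_map={k: v for k, v in snv_map.items() if k in _SNV_TYPES},
        dot_colour_map={k: v for k, v in cna_map.items() if k in _CNA_TYPES},
    )


def fig1_gallery(seed: int = DEFAULT_SEED) -> dict:
    """(ChartSpec, data) pairs for the full chart-type gallery."""
    data = make_fig1_datasets(seed)
    specs = {
        "density": ChartSpec(
            "density", data_binding={"value": "value", "group": "group"},
            x_axis=AxisSpec(label="expression"), y_axis=AxisSpec(label="density"),
        ),
        "boxplot": ChartSpec(
            "boxplot", data_binding={"value": "value", "group": "group"},
            y_axis=AxisSpec(label="expression"),
        ),
        "violin": ChartSpec(
            "violin", data_binding={"value": "value", "group": "group"},
            y_axis=AxisSpec(label="expression"),
        ),
        "segplot": ChartSpec(
            "segplot",
            data_binding={"category": "category", "centre": "centre",
                          "lo": "lo", "hi": "hi"},
            x_axis=AxisSpec(label="log fold change"),
        ),
        "stripplot": ChartSpec(
            "stripplot", data_binding={"value": "value", "group": "group"},
            y_axis=AxisSpec(label="expression"),
        ),
        "barplot": ChartSpec(
            "barplot", data_binding={"category": "category", "value": "value"},
            y_axis=AxisSpec(label="count"),
        ),
        "scatterplot": ChartSpec(
            "scatterplot", data_binding={"x": "x", "y": "y"},
            x_axis=AxisSpec(label="x"), y_axis=AxisSpec(label="y"),
        ),
        "histogram": ChartSpec(
            "histogram", data_binding={"value": "value"},
            aesthetics={"bins": 15}, y_axis=AxisSpec(label="count"),
        ),
        "qq_fit": ChartSpec(
            "qq_fit", data_binding={"value": "value"},
            aesthetics={"distribution": "norm"},
            x_axis=AxisSpec(label="theoretical quantiles"),
            y_axis=AxisSpec(label="sample quantiles"),
        ),
        "qq_comparison": ChartSpec(
            "qq_comparison", data_binding={"a": "a", "b": "b"},
            x_axis=AxisSpec(label="sample A"), y_axis=AxisSpec(label="sample B"),
        ),
        "manhattan": ChartSpec(
            "manhattan",
            data_binding={"chromosome": "chromosome", "position": "position",
                          "p_value": "p_value"},
            aesthetics={"chrom_order": ["1", "2", "3"],
                        "significance_line": 5e-8},
            x_axis=AxisSpec(label="chromosome"),
            y_axis=AxisSpec(label="-log10 p"),
        ),
        "polygonplot": ChartSpec(
            "polygonplot",
            data_binding={"x": "x", "series": ["clone_a", "clone_b"]},
            x_axis=AxisSpec(label="time"), y_axis=AxisSpec(label="abundance"),
        ),
        "heatmap": ChartSpec(
            "heatmap", aesthetics={"colour_scheme": "RdBu"},
        ),
        "dotmap": ChartSpec("dotmap"),
        "hexbinplot": ChartSpec(
            "hexbinplot", data_binding={"x": "x", "y": "y"},
            aesthetics={"nbins": 10},
            x_axis=AxisSpec(label="x"), y_axis=AxisSpec(label="y"),
        ),
    }
    from dataclasses import replace

    return {
        name: (replace(specs[name], data=name), data[name]) for name in specs
    }


# ---------------------------------------------------------------------------
# the six-panel cohort figure
# ---------------------------------------------------------------------------


def cohort_figure(
    dataset: MutationDataset | None = None,
    theme: Theme | None = None,
    seed: int = DEFAULT_SEED,
) -> ComposedFigure:
    """The oncoprint-style multi-panel cohort figure.

    Six panels: a central dotmap of SNVs (cell shading) and CNAs (inset
    dots) per gene and patient; a clinical-covariate heatmap below sharing
    the patient axis; a horizontal barplot on the right giving the
    percentage of patients altered per gene, sharing the gene axis; a
    stacked barplot on top counting SNVs and CNAs per patient; a second
    stacked barplot of per-patient base-change proportions; and the mutation
    legend on the left.
    """
    ds = dataset or make_mutation_dataset(seed=seed)
    patients = ds.patients
    genes = ds.genes

    dot = _dotmap_from_cohort(ds)
    dotmap_panel = create_chart(
        ChartSpec("dotmap", aesthetics={"x_tick_rotation": 90}), dot
    )

    counts = ds.derived["per_patient_counts"]
    counts_df = pd.DataFrame(
        {
            "patient": list(patients) * 2,
            "kind": ["snv"] * len(patients) + ["cna"] * len(patients),
            "count": list(counts["snv"]) + list(counts["cna"]),
        }
    )
    counts_panel = create_chart(
        ChartSpec(
            "barplot",
            data_binding={"category": "patient", "value": "count", "group": "kind"},
            aesthetics={"group_colours": {"snv": "#2166AC", "cna": "#B2182B"}},
            y_axis=AxisSpec(label="mutations"),
        ),
        counts_df,
    )

    props = ds.derived["basechange_props"]
    base_pal = force_colour_scheme("base.changes")
    base_map = {lab: col.to_hex() for lab, col in zip(base_pal.labels, base_pal.colours)}
    rows = []
    for patient in patients:
        for cls in BASE_CHANGES:
            rows.append(
                {"patient": patient, "class": cls, "prop": props.loc[patient, cls]}
            )
    props_panel = create_chart(
        ChartSpec(
            "barplot",
            data_binding={"category": "patient", "value": "prop", "group": "class"},
            aesthetics={"group_colours": base_map},
            y_axis=AxisSpec(label="SNV fraction"),
        ),
        pd.DataFrame(rows),
    )

    clin_matrix = pd.DataFrame(
        {p: [ds.clinical.loc[p, "sex"], ds.clinical.loc[p, "stage"],
             ds.clinical.loc[p, "msi_status"]] for p in patients},
        index=["sex", "stage", "MSI"],
    )
    sex_pal = force_colour_scheme("sex")
    stage_pal = force_colour_scheme("tumour.stage")
    msi_pal = force_colour_scheme("msi.status")
    clin_map = {}
    for pal in (sex_pal, stage_pal, msi_pal):
        clin_map.update(
            {lab: col.to_hex() for lab, col in zip(pal.labels, pal.colours)}
        )
    clinical_panel = create_chart(
        ChartSpec(
            "heatmap",
            aesthetics={"colour_map": clin_map, "x_tick_rotation": 90},
        ),
        clin_matrix,
    )

    pct = ds.derived["per_gene_pct"]
    pct_panel = create_chart(
        ChartSpec(
            "barplot",
            data_binding={"category": "gene", "value": "pct"},
            aesthetics={"orientation": "horizontal", "colour": "#4D4D4D"},
            x_axis=AxisSpec(label="% altered"),
        ),
        pd.DataFrame({"gene": genes, "pct": [pct[g] for g in genes]}),
    )

    snv_pal = force_colour_scheme("mutation.types")
    entries = [
        (lab, col, "box")
        for lab, col in zip(snv_pal.labels, snv_pal.colours)
        if lab in _SNV_TYPES
    ] + [
        (f"CNA {lab}", col, "dot")
        for lab, col in zip(
            force_colour_scheme("cna.types").labels,
            force_colour_scheme("cna.types").colours,
        )
        if lab in _CNA_TYPES
    ]
    legend_panel = create_legend(LegendSpec.make(entries, title="mutation type"))

    panels = [
        counts_panel,    # 0: top
        props_panel,     # 1: second from top
        legend_panel,    # 2: left
        dotmap_panel,    # 3: centre
        pct_panel,       # 4: right
        clinical_panel,  # 5: bottom
    ]
    layout = MultiplotLayout.make(
        n_rows=4,
        n_cols=3,
        placements=[
            (0, 0, 1),  # counts barplot, top centre
            (1, 1, 1),  # base-change proportions
            (2, 2, 0),  # legend, left of the dotmap
            (3, 2, 1),  # dotmap, centre
            (4, 2, 2),  # per-gene percentage, right
            (5, 3, 1),  # clinical heatmap, bottom
        ],
        row_heights=(0.28, 0.28, 1.0, 0.22),
        col_widths=(0.28, 1.0, 0.3),
        shared_x_groups=[(0, 1, 3, 5)],
        shared_y_groups=[(3, 4)],
        spacing=0.012,
    )
    return compose(panels, layout, theme=theme, figure_size=(9, 7))


def write_fixture_files(directory, seed: int = DEFAULT_SEED) -> dict[str, Path]:
    """Write every gallery dataset as CSV files consumable by the CLI.

    The dotmap dataset is written as paired cell/dot category matrices.
    Returns a mapping from dataset name to written path(s).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    data = make_fig1_datasets(seed)
    written: dict[str, Path] = {}
    for name, obj in data.items():
        if isinstance(obj, DotmapData):
            for part, matrix in (
                ("cell", obj.cell_categories),
                ("dot", obj.dot_categories),
            ):
                path = directory / f"{name}_{part}.csv"
                pd.DataFrame(
                    matrix, index=obj.row_labels, columns=obj.col_labels
                ).to_csv(path)
                written[f"{name}_{part}"] = path
        else:
            path = directory / f"{name}.csv"
            index = name == "heatmap"
            obj.to_csv(path, index=index)
            written[name] = path
    return written
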