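"""Synthetic RNA-seq count matrices for the MYB5a knockdown experiment.

Emulates the downstream product of the study design — three wild-type and
three RNAi petal libraries — as a genes x samples integer count matrix with
a known effect-size structure:

* six anthocyanin regulators (MYB5a, two bHLH copies, a WD40, and the two
  R3 MYB repressor homeologs RTO1/RTO2), with fold-downs 3, 2.5, 2.5, 2.5,
  19 and 29 in the knockdown;
* 30 biosynthetic-enzyme genes across the six core classes, split into
  early genes (CHS, CHI, F3H — mixed up/down/no-change response) and late
  genes (DFR, ANS, UF3GT — coordinately down);
* a configurable pool of null background genes.

Counts are negative-binomial with mean ``depth_s * baseline_g * FC_g`` (the
fold change applied only in RNAi samples) and variance ``mu + alpha*mu**2``;
``alpha = 0`` degenerates to Poisson.  Everything is deterministic given the
configuration and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "REGULATOR_SUBROLES",
    "EBG_CLASSES",
    "LBG_CLASSES",
    "ENZYME_CLASSES",
    "EffectPreset",
    "PanelConfig",
    "GenePanel",
    "CountMatrix",
    "build_panel",
    "generate_counts",
]

REGULATOR_SUBROLES = ("MYB5a", "bHLH1", "bHLH2", "WD40a", "RTO1", "RTO2")
EBG_CLASSES = ("CHS", "CHI", "F3H")
LBG_CLASSES = ("DFR", "ANS", "UF3GT")
ENZYME_CLASSES = EBG_CLASSES + LBG_CLASSES

WILD_TYPE = "wild_type"
RNAI = "rnai"

#: Mean-count ceiling above which negative-binomial sampling is refused.
MAX_MEAN = 1e12


@dataclass(frozen=True)
class EffectPreset:
    """True fold changes (RNAi vs wild-type scale: FC < 1 means down).

    ``fig5c`` carries the knockdown experiment's regulator fold-downs
    (MYB5a threefold; bHLH/WD40 2.5-fold, the midpoint of the observed two-
    to threefold range; RTO homeologs 19- and 29-fold — the assignment of
    19 to RTO1 and 29 to RTO2 is an arbitrary labelling of the two
    homeologs).  LBG copies share a fourfold knockdown and EBG copies cycle
    through up / down / no-change; these two are qualitative-structure
    choices, not measured values.
    """

    name: str
    regulator_fold_down: dict = field(default_factory=dict)
    lbg_fold_down: float = 4.0
    ebg_fold_cycle: tuple = (1.5, 1 / 1.5, 1.0)

    @classmethod
    def fig5c(cls) -> "EffectPreset":
        return cls(
            name="fig5c",
            regulator_fold_down={
                "MYB5a": 3.0, "bHLH1": 2.5, "bHLH2": 2.5, "WD40a": 2.5,
                "RTO1": 19.0, "RTO2": 29.0,
            },
        )

    @classmethod
    def null(cls) -> "EffectPreset":
        """No true effects anywhere; for FDR calibration."""
        return cls(
            name="null",
            regulator_fold_down={s: 1.0 for s in REGULATOR_SUBROLES},
            lbg_fold_down=1.0,
            ebg_fold_cycle=(1.0,),
        )


#: Default enzyme copy numbers: 30 genes total, with each early class
#: having more than the two homeologous copies expected in a tetraploid.
DEFAULT_ENZYME_COPIES = {"CHS": 7, "CHI": 6, "F3H": 5, "DFR": 4, "ANS": 4, "UF3GT": 4}

#: Baseline mean counts (at unit depth) for the six regulators.  The RTO
#: baselines are high enough that a 19-29-fold knockdown still leaves
#: estimable counts in the RNAi samples.
DEFAULT_REGULATOR_BASELINES = {
    "MYB5a": 500.0, "bHLH1": 400.0, "bHLH2": 350.0, "WD40a": 600.0,
    "RTO1": 800.0, "RTO2": 1200.0,
}


@dataclass(frozen=True)
class PanelConfig:
    """Gene-panel construction settings (all deterministic given a config)."""

    effects: EffectPreset = field(default_factory=EffectPreset.fig5c)
    enzyme_copies: dict = field(default_factory=lambda: dict(DEFAULT_ENZYME_COPIES))
    regulator_baselines: dict = field(default_factory=lambda: dict(DEFAULT_REGULATOR_BASELINES))
    enzyme_baseline: float = 300.0
    n_background: int = 2000
    background_baseline_range: tuple = (5.0, 2000.0)
    length_range: tuple = (500.0, 5000.0)
    panel_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_background < 0:
            raise ValueError("n_background must be >= 0")
        if self.enzyme_baseline <= 0:
            raise ValueError("enzyme_baseline must be > 0")
        if any(b <= 0 for b in self.regulator_baselines.values()):
            raise ValueError("regulator baselines must be > 0")
        if self.background_baseline_range[0] <= 0 or self.length_range[0] <= 0:
            raise ValueError("baseline and length ranges must be positive")

    def with_(self, **updates) -> "PanelConfig":
        return replace(self, **updates)


@dataclass(frozen=True)
class GenePanel:
    """Per-gene truth table: roles, lengths, baselines and true fold changes.

    ``table`` columns: gene_id, role (regulator / EBG / LBG / background),
    subrole (regulator name or enzyme class), copy_index, length,
    baseline, true_fc.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene_id", "role", "subrole", "copy_index", "length", "baseline", "true_fc"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"panel table missing columns: {sorted(missing)}")
        if (self.table["length"] <= 0).any() or (self.table["baseline"] <= 0).any():
            raise ValueError("gene lengths and baselines must be > 0")
        if (self.table["true_fc"] <= 0).any():
            raise ValueError("true fold changes must be > 0")
        reg = self.table[self.table["role"] == "regulator"]
        if reg["subrole"].duplicated().any():
            raise ValueError("regulator subroles must be unique")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def gene_ids(self) -> list[str]:
        return self.table["gene_id"].tolist()

    def genes_with_role(self, role: str) -> pd.DataFrame:
        return self.table[self.table["role"] == role]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "GenePanel":
        return cls(pd.read_csv(path))


def build_panel(config: PanelConfig | None = None) -> GenePanel:
    """Assemble the gene panel from a configuration (or its defaults).

    Regulators get their preset fold-downs; enzyme copies are assigned the
    LBG fold-down or the cycling EBG response; background genes are null
    (``true_fc = 1``) with baselines drawn log-uniformly and lengths drawn
    uniformly from the configured ranges using the panel's own fixed seed,
    so the same config always yields the same panel.
    """
    cfg = config or PanelConfig()
    eff = cfg.effects
    rng = np.random.default_rng(cfg.panel_seed)
    rows = []

    for subrole in REGULATOR_SUBROLES:
        fold_down = eff.regulator_fold_down.get(subrole, 1.0)
        rows.append({
            "gene_id": f"REG_{subrole}", "role": "regulator", "subrole": subrole,
            "copy_index": 1, "baseline": cfg.regulator_baselines[subrole],
            "true_fc": 1.0 / fold_down,
        })
    for cls_name in ENZYME_CLASSES:
        n_copies = int(cfg.enzyme_copies.get(cls_name, 0))
        role = "EBG" if cls_name in EBG_CLASSES else "LBG"
        for copy in range(1, n_copies + 1):
            if role == "LBG":
                fc = 1.0 / eff.lbg_fold_down
            else:
                fc = eff.ebg_fold_cycle[(copy - 1) % len(eff.ebg_fold_cycle)]
            rows.append({
                "gene_id": f"{cls_name}_{copy}", "role": role, "subrole": cls_name,
                "copy_index": copy, "baseline": cfg.enzyme_baseline, "true_fc": fc,
            })
    if cfg.n_background:
        lo, hi = cfg.background_baseline_range
        baselines = np.exp(rng.uniform(math.log(lo), math.log(hi), size=cfg.n_background))
        for j in range(cfg.n_background):
            rows.append({
                "gene_id": f"BG_{j + 1:05d}", "role": "background", "subrole": "background",
                "copy_index": 1, "baseline": float(baselines[j]), "true_fc": 1.0,
            })
    table = pd.DataFrame(rows)
    table["length"] = rng.uniform(*cfg.length_range, size=len(table)).round()
    table = table[["gene_id", "role", "subrole", "copy_index", "length", "baseline", "true_fc"]]
    return GenePanel(table)


@dataclass
class CountMatrix:
    """Genes x samples integer counts with group labels and depth factors."""

    counts: pd.DataFrame
    groups: pd.Series
    depth_factors: pd.Series

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.groups.index):
            raise ValueError("count columns and group index disagree")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        sizes = self.groups.value_counts()
        if (sizes < 2).any():
            raise ValueError("each group needs >= 2 samples for dispersion estimation")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def write(self, counts_path, groups_path) -> None:
        """Counts as TSV (gene id first column); groups as CSV."""
        self.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
        self.groups.rename("group").to_csv(groups_path, index_label="sample")

    @classmethod
    def read(cls, counts_path, groups_path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        groups = pd.read_csv(groups_path, index_col=0)["group"]
        depths = pd.Series(1.0, index=counts.columns)
        return cls(counts=counts, groups=groups, depth_factors=depths)


def generate_counts(
    panel: GenePanel,
    n_per_group: int = 3,
    depths: np.ndarray | None = None,
    alpha: float = 0.05,
    seed: int = 0,
    depth_sigma: float = 0.1,
) -> CountMatrix:
    """Draw a seeded negative-binomial count matrix from the panel truth.

    Sample ``s`` of gene ``g`` has mean ``depth_s * baseline_g`` in wild
    type and ``depth_s * baseline_g * true_fc_g`` in the RNAi group, with
    variance ``mu + alpha * mu**2``.  ``depths`` defaults to log-normal
    factors around 1 (sigma ``depth_sigma``) drawn from the same seed.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if alpha < 0:
        raise ValueError("dispersion alpha must be >= 0")
    rng = np.random.default_rng(seed)
    n_samples = 2 * n_per_group
    if depths is None:
        depths = np.exp(rng.normal(0.0, depth_sigma, size=n_samples))
    depths = np.asarray(depths, dtype=float)
    if depths.shape != (n_samples,) or (depths <= 0).any():
        raise ValueError(f"depths must be {n_samples} positive factors")

    samples = [f"wt_{j + 1}" for j in range(n_per_group)] + \
              [f"rnai_{j + 1}" for j in range(n_per_group)]
    group = np.array([WILD_TYPE] * n_per_group + [RNAI] * n_per_group)

    baseline = panel.table["baseline"].to_numpy()[:, None]
    fc = panel.table["true_fc"].to_numpy()[:, None]
    mu = baseline * depths[None, :] * np.where(group[None, :] == RNAI, fc, 1.0)
    if (mu > MAX_MEAN).any():
        raise ValueError(f"mean counts exceed {MAX_MEAN:g}; reduce baselines or depths")

    if alpha == 0:
        draws = rng.poisson(mu)
    else:
        size = 1.0 / alpha
        draws = rng.negative_binomial(size, size / (size + mu))
    counts = pd.DataFrame(draws, index=pd.Index(panel.gene_ids, name="gene_id"),
                          columns=samples)
    return CountMatrix(
        counts=counts,
        groups=pd.Series(group, index=samples, name="group"),
        depth_factors=pd.Series(depths, index=samples, name="depth"),
    )
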