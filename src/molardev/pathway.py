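"""Pathway-target polarity classification and activity tallies.

Given a curated table of perturbation-response interactions (gene, pathway,
tissue, perturbation, response, source) and a differential-expression table
between two strains, each DE gene is classified as a positive target (up on
pathway activation, or down on inhibition) or a negative target (down on
activation, or up on inhibition) of the pathway. Genes whose polarity
conflicts between tissues are excluded (whole tooth germs mix both
tissues); conflicts between sources resolve toward a designated primary
source. The classified DE genes are then tallied as evidence for weaker
versus greater pathway activity in the focal strain and the tally is tested
against a 50:50 split with a chi-square goodness-of-fit test.

The sign convention linking log2 fold change to "weaker"/"greater" activity
is an explicit flag: ``convention="caption"`` (default) reads positive
log2FC as higher expression in the focal strain, so an upregulated positive
target argues for greater activity there; ``convention="text"`` inverts the
mapping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .stats import chisq_gof

logger = logging.getLogger(__name__)

__all__ = [
    "PolarityTally",
    "PERTURBATION_DIRECTION",
    "load_example_interactions",
    "classify_targets",
    "tally_polarity",
    "test_polarity",
]

REQUIRED_COLUMNS = ["gene", "pathway", "tissue", "perturbation", "response", "source"]

# perturbation label -> whether it activates or inhibits the pathway
PERTURBATION_DIRECTION = {
    "activation": "activation",
    "inhibition": "inhibition",
    "+": "activation",
    "-": "inhibition",
    "ligand_treatment": "activation",
    "bmp4_treatment": "activation",
    "wnt_treatment": "activation",
    "gsk3b_inhibition": "activation",
    "ctnnb1_overexpression": "activation",
    "knockout": "inhibition",
    "receptor_knockout": "inhibition",
    "bmp4_knockout": "inhibition",
    "ctnnb1_knockout": "inhibition",
    "dkk1_overexpression": "inhibition",
    "lef1_knockout": "inhibition",
}

VALID_RESPONSES = {"+", "-", "o"}


@dataclass
class PolarityTally:
    """Counts of DE target genes arguing for weaker vs greater activity."""

    pathway: str
    n_weaker: int
    n_greater: int
    contributions: pd.DataFrame  # gene, target_class, log2fc, padj, supports

    @property
    def counts(self) -> tuple[int, int]:
        return self.n_weaker, self.n_greater


def load_example_interactions() -> pd.DataFrame:
    """The packaged synthetic interaction table (format demonstration only)."""
    with resources.files("molardev.data").joinpath("interactions_synthetic.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def _row_polarity(direction: str, response: str) -> str:
    if response == "+":
        return "positive" if direction == "activation" else "negative"
    return "negative" if direction == "activation" else "positive"


def classify_targets(
    interactions: pd.DataFrame, primary_source: str | None = None
) -> pd.DataFrame:
    """Classify each (pathway, gene) as positive/negative target or excluded.

    Returns a DataFrame with columns pathway, gene, target_class
    (positive / negative / excluded_tissue_conflict / excluded_no_signal)
    and notes. Row order of the input is irrelevant.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in interactions.columns]
    if missing:
        raise ValueError(f"interaction table lacks columns: {missing}")
    bad_resp = set(interactions["response"]) - VALID_RESPONSES
    if bad_resp:
        raise ValueError(f"unknown response codes: {sorted(bad_resp)} (use +, -, o)")
    unmapped = sorted(
        set(interactions["perturbation"]) - set(PERTURBATION_DIRECTION)
    )
    if unmapped:
        raise ValueError(
            f"unmapped perturbation types: {unmapped}; extend PERTURBATION_DIRECTION"
        )

    df = interactions.copy()
    df["direction"] = df["perturbation"].map(PERTURBATION_DIRECTION)

    rows = []
    for (pathway, gene), grp in sorted(
        df.groupby(["pathway", "gene"], sort=False), key=lambda kv: kv[0]
    ):
        informative = grp[grp["response"] != "o"]
        if informative.empty:
            rows.append(
                dict(pathway=pathway, gene=gene, target_class="excluded_no_signal",
                     notes="all responses 'o'")
            )
            continue
        calls = informative.assign(
            polarity=[
                _row_polarity(d, r)
                for d, r in zip(informative["direction"], informative["response"])
            ]
        )
        notes = []
        # source conflicts resolve toward the primary source
        if calls["polarity"].nunique() > 1 and primary_source is not None:
            primary = calls[calls["source"] == primary_source]
            if not primary.empty and calls["source"].nunique() > 1:
                per_tissue_ok = all(
                    primary[primary["tissue"] == t]["polarity"].nunique() <= 1
                    for t in primary["tissue"].unique()
                )
                if per_tissue_ok:
                    calls = primary
                    notes.append(f"source conflict resolved toward {primary_source!r}")
        per_tissue = calls.groupby("tissue")["polarity"].agg(set)
        tissue_calls = set()
        intratissue_conflict = False
        for t, pol in per_tissue.items():
            if len(pol) > 1:
                intratissue_conflict = True
            tissue_calls |= pol
        if len(tissue_calls) > 1:
            rows.append(
                dict(pathway=pathway, gene=gene,
                     target_class="excluded_tissue_conflict",
                     notes="; ".join(notes + ["opposite polarity across tissues"
                                              if not intratissue_conflict
                                              else "unresolved polarity conflict"]))
            )
            continue
        rows.append(
            dict(pathway=pathway, gene=gene, target_class=tissue_calls.pop(),
                 notes="; ".join(notes))
        )
    return pd.DataFrame(rows, columns=["pathway", "gene", "target_class", "notes"])


def tally_polarity(
    classes: pd.DataFrame,
    de_table: pd.DataFrame,
    pathway: str,
    alpha: float = 0.05,
    convention: str = "caption",
) -> PolarityTally:
    """Tally DE targets supporting weaker vs greater pathway activity.

    ``de_table`` needs columns gene, log2fc, padj; only genes with
    padj < alpha and a positive/negative target class contribute. Classified
    genes absent from the DE table are skipped with a log entry.
    """
    if convention not in ("caption", "text"):
        raise ValueError("convention must be 'caption' or 'text'")
    for col in ("gene", "log2fc", "padj"):
        if col not in de_table.columns:
            raise ValueError(f"DE table lacks column {col!r}")
    cls = classes[
        (classes["pathway"] == pathway)
        & classes["target_class"].isin(["positive", "negative"])
    ]
    de = de_table.set_index("gene")
    contributions = []
    n_weaker = n_greater = 0
    for _, row in cls.iterrows():
        gene = row["gene"]
        if gene not in de.index:
            logger.info("gene %s classified but absent from the DE table; skipped", gene)
            continue
        log2fc = float(de.loc[gene, "log2fc"])
        padj = float(de.loc[gene, "padj"])
        if not padj < alpha:
            continue
        up = log2fc > 0
        positive = row["target_class"] == "positive"
        # caption convention: up positive target -> greater activity in the
        # focal strain
        greater = up == positive
        if convention == "text":
            greater = not greater
        if greater:
            n_greater += 1
        else:
            n_weaker += 1
        contributions.append(
            dict(gene=gene, target_class=row["target_class"], log2fc=log2fc,
                 padj=padj, supports="greater" if greater else "weaker")
        )
    return PolarityTally(
        pathway=pathway,
        n_weaker=n_weaker,
        n_greater=n_greater,
        contributions=pd.DataFrame(
            contributions,
            columns=["gene", "target_class", "log2fc", "padj", "supports"],
        ),
    )


def test_polarity(tally: PolarityTally) -> tuple[float, float]:
    """Chi-square goodness-of-fit of the tally against a 50:50 split."""
    if tally.n_weaker + tally.n_greater == 0:
        raise ValueError("empty tally: no classified DE targets")
    chi2, _, p = chisq_gof((tally.n_weaker, tally.n_greater))
    return chi2, p
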