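"""Meta-analysis arithmetic over aggregated modulation-efficacy tables.

Efficacy is expressed as % of the control GABA current (100 = no
modulation).  Receptor compositions are written as compact subunit tokens
over the alphabet {a1..a6, b1..b3, g2, d} — e.g. ``a1b3``, ``a2b3g2``,
``a1b3d`` — normalized to the canonical order α, β, γ2/δ.  The module
computes fold changes between receptor variants (preferring the 10 μM record
when a compound was measured at several concentrations), summaries of the
impact of adding a third-subunit class (γ2 or δ) to binary αβ receptors,
a NAM / silent / PAM classification, and similarity-ordered heatmap layouts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist


class EfficacyError(ValueError):
    pass


_SUBUNIT_RE = re.compile(r"(a[1-6]|b[1-3]|g2|d)")
REQUIRED_COLUMNS = ("compound", "receptor", "concentration_uM",
                    "efficacy_pct", "is_max", "source")


def normalize_receptor(token: str) -> str:
    """Validate a receptor token and normalize it to canonical subunit order.

    A valid composition has at least one α and one β subunit and at most one
    of γ2 / δ; subunits are ordered α, β, then γ2/δ.
    """
    token = token.strip().lower()
    parts = _SUBUNIT_RE.findall(token)
    if "".join(parts) != token or not parts:
        raise EfficacyError(f"unparseable receptor token {token!r}")
    alphas = sorted(p for p in parts if p.startswith("a"))
    betas = sorted(p for p in parts if p.startswith("b"))
    third = [p for p in parts if p in ("g2", "d")]
    if not alphas or not betas:
        raise EfficacyError(
            f"receptor {token!r} must contain an α and a β subunit"
        )
    if len(third) > 1:
        raise EfficacyError(f"receptor {token!r} has multiple γ2/δ subunits")
    return "".join(alphas + betas + third)


@dataclass(frozen=True)
class EfficacyRecord:
    compound: str
    receptor: str          # canonical token
    concentration_uM: float
    efficacy_pct: float    # % of control GABA current; 100 = no modulation
    is_max_estimate: bool = False
    source: str = ""

    def __post_init__(self) -> None:
        if not self.efficacy_pct > 0:
            raise EfficacyError(
                f"{self.compound}/{self.receptor}: efficacy must be > 0, "
                f"got {self.efficacy_pct}"
            )


def load_efficacy(path) -> list[EfficacyRecord]:
    """Load an efficacy table CSV (columns: compound, receptor,
    concentration_uM, efficacy_pct, is_max, source)."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise EfficacyError(f"{path}: missing columns {missing}")
    records = []
    errors = []
    for idx, row in df.iterrows():
        try:
            records.append(EfficacyRecord(
                compound=str(row["compound"]),
                receptor=normalize_receptor(str(row["receptor"])),
                concentration_uM=float(row["concentration_uM"]),
                efficacy_pct=float(row["efficacy_pct"]),
                is_max_estimate=bool(row["is_max"]),
                source=str(row["source"]),
            ))
        except (EfficacyError, ValueError) as exc:
            errors.append(f"row {idx}: {exc}")
    if errors:
        raise EfficacyError(f"{path}: invalid rows:\n" + "\n".join(errors))
    return records


def _cell(records: list[EfficacyRecord], compound: str,
          receptor: str) -> dict[float, float]:
    """Concentration → efficacy for one (compound, receptor) cell."""
    receptor = normalize_receptor(receptor)
    return {r.concentration_uM: r.efficacy_pct for r in records
            if r.compound == compound and r.receptor == receptor}


def fold_change(records: list[EfficacyRecord], compound: str,
                receptor_test: str, receptor_ref: str,
                preferred_uM: float = 10.0) -> float:
    """Efficacy ratio test / reference for one compound.

    When both cells carry a record at the preferred concentration (10 μM by
    convention), those are used; otherwise the highest concentration present
    in both cells.  A missing cell, or cells with no shared concentration,
    is an error naming the gap.
    """
    test = _cell(records, compound, receptor_test)
    ref = _cell(records, compound, receptor_ref)
    for name, cell in (("test", test), ("reference", ref)):
        if not cell:
            raise EfficacyError(
                f"{compound}: no efficacy for the {name} receptor "
                f"({receptor_test if name == 'test' else receptor_ref})"
            )
    if preferred_uM in test and preferred_uM in ref:
        conc = preferred_uM
    else:
        shared = set(test) & set(ref)
        if not shared:
            raise EfficacyError(
                f"{compound}: no shared concentration between "
                f"{receptor_test} ({sorted(test)}) and "
                f"{receptor_ref} ({sorted(ref)})"
            )
        conc = max(shared)
    return test[conc] / ref[conc]


def subunit_impact_summary(records: list[EfficacyRecord],
                           added_subunit: str,
                           reference_beta: str = "b3") -> dict:
    """Impact of adding γ2 or δ to binary αβ receptors.

    For every (compound, αx) with both the reference αxβ3 and the extended
    αxβ3+subunit measured, computes the fold change; returns the mean and
    max over eligible pairs plus the per-pair table.
    """
    if added_subunit not in ("g2", "d"):
        raise EfficacyError(f"added_subunit must be 'g2' or 'd', got {added_subunit!r}")
    pairs = []
    compounds = sorted({r.compound for r in records})
    alphas = [f"a{i}" for i in range(1, 7)]
    for compound in compounds:
        for alpha in alphas:
            ref = f"{alpha}{reference_beta}"
            ext = f"{alpha}{reference_beta}{added_subunit}"
            try:
                fold = fold_change(records, compound, ext, ref)
            except EfficacyError:
                continue
            pairs.append({"compound": compound, "alpha": alpha,
                          "reference": ref, "extended": ext, "fold": fold})
    if not pairs:
        raise EfficacyError(
            f"no (compound, α-isoform) pair has both αx{reference_beta} and "
            f"αx{reference_beta}{added_subunit} measured"
        )
    folds = np.array([p["fold"] for p in pairs])
    return {
        "added_subunit": added_subunit,
        "mean_fold": float(folds.mean()),
        "max_fold": float(folds.max()),
        "n_pairs": len(pairs),
        "table": pd.DataFrame(pairs),
    }


def classify_modulation(efficacy_pct: float,
                        thresholds: tuple[float, float] = (80.0, 120.0)) -> str:
    """NAM / silent / PAM classification of an efficacy value.

    Strictly below the low threshold → NAM, strictly above the high
    threshold → PAM, the closed band in between → silent.  The default
    (80, 120)% band treats modest deviations from the 100% no-modulation
    point as functionally silent; the cutoffs are a convention, not a
    measured boundary.
    """
    lo, hi = thresholds
    if lo >= hi:
        raise EfficacyError(f"thresholds must satisfy lo < hi, got {thresholds}")
    if not efficacy_pct > 0:
        raise EfficacyError(f"efficacy must be > 0, got {efficacy_pct}")
    if efficacy_pct < lo:
        return "NAM"
    if efficacy_pct > hi:
        return "PAM"
    return "silent"


def efficacy_matrix(records: list[EfficacyRecord],
                    preferred_uM: float = 10.0) -> pd.DataFrame:
    """Compounds × receptors efficacy matrix (NaN where unmeasured);
    per cell the preferred-concentration record, else the highest."""
    cells: dict[tuple[str, str], dict[float, float]] = {}
    for r in records:
        cells.setdefault((r.compound, r.receptor), {})[r.concentration_uM] = r.efficacy_pct
    compounds = sorted({c for c, _ in cells})
    receptors = sorted({r for _, r in cells})
    M = pd.DataFrame(np.nan, index=compounds, columns=receptors)
    for (c, r), byconc in cells.items():
        conc = preferred_uM if preferred_uM in byconc else max(byconc)
        M.loc[c, r] = byconc[conc]
    return M


def similarity_order(matrix: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Row and column orders for a similarity-ordered heatmap.

    Average-linkage hierarchical clustering with Euclidean distance on the
    available cells; missing cells are filled with the column (for rows) or
    row (for columns) mean for the ordering only — never for statistics.
    Deterministic leaf order.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise EfficacyError("similarity ordering needs >= 2 rows and columns")
    # canonicalize by label so the leaf order is invariant to input row and
    # column permutations
    matrix = matrix.sort_index(axis=0).sort_index(axis=1)
    empty_rows = matrix.index[matrix.isna().all(axis=1)].tolist()
    empty_cols = matrix.columns[matrix.isna().all(axis=0)].tolist()
    if empty_rows or empty_cols:
        raise EfficacyError(
            f"all-missing rows {empty_rows} / columns {empty_cols}"
        )

    def _leaf_order(M: np.ndarray) -> np.ndarray:
        col_means = np.nanmean(M, axis=0)
        filled = np.where(np.isnan(M), col_means[None, :], M)
        return leaves_list(linkage(pdist(filled), method="average"))

    row_order = [matrix.index[i] for i in _leaf_order(matrix.to_numpy())]
    col_order = [matrix.columns[i] for i in _leaf_order(matrix.to_numpy().T)]
    return row_order, col_order
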