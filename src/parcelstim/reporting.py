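"""Published-cohort target table and its summary arithmetic.

The package ships the study cohort's target table (26 patients, 76
targets) transcribed verbatim: 19 rows of (label, protocol, full name,
location, network, patient count). The row counts sum to 76, split 69
cTBS / 7 iTBS in agreement with the demographics table. One printed
inconsistency is preserved and flagged rather than reconciled: the row
labelled "L46 (iTBS)" carries the full name "Right area 46" (identical
to the distinct "R46 (iTBS)" row), so its hemisphere is ambiguous as
printed. The results text's "66 cTBS targets (87%)" also disagrees with
the tables' 69; the tables are taken as authoritative here.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

COHORT_TOTAL_TARGETS = 76  # printed header/denominator


class FixtureError(ValueError):
    pass


def load_cohort_targets() -> pd.DataFrame:
    """Verbatim target table: one row per (label, protocol) as printed."""
    with resources.files("parcelstim.data").joinpath(
            "cohort_targets.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    _validate(df)
    return df


def _validate(df: pd.DataFrame) -> None:
    required = {"label", "protocol", "full_name", "location", "network",
                "n_patients", "outside_dlpfc"}
    if not required.issubset(df.columns):
        raise FixtureError(f"missing columns: {required - set(df.columns)}")
    if len(df) != 19:
        raise FixtureError(f"expected 19 rows, got {len(df)}")
    if (df["n_patients"] < 0).any():
        raise FixtureError("negative patient count")
    if not set(df["protocol"]) <= {"cTBS", "iTBS"}:
        raise FixtureError("unknown protocol label")


def inconsistent_rows(df: pd.DataFrame) -> pd.DataFrame:
    """Rows whose label hemisphere contradicts the printed full name, or
    whose (full_name, protocol) is printed under more than one label."""
    hemi_label = df["label"].str[0]
    hemi_name = df["full_name"].str.extract(r"\b(Left|Right)\b",
                                            expand=False).str[0]
    mismatch = hemi_name.notna() & (hemi_label != hemi_name)
    dup = df.duplicated(subset=["full_name", "protocol"], keep=False)
    return df[mismatch | dup]


def cohort_target_summary(df: pd.DataFrame = None) -> dict:
    """Totals, per-protocol and per-parcel counts, and percentages.

    Row counts sum to the printed total of 76; percentages use that
    denominator at one decimal, matching the printed style.
    """
    if df is None:
        df = load_cohort_targets()
    _validate(df)
    total = int(df["n_patients"].sum())
    per_protocol = {p: int(df.loc[df['protocol'] == p, 'n_patients'].sum())
                    for p in ("cTBS", "iTBS")}
    per_label = (df.groupby("label")["n_patients"].sum()
                 .astype(int).to_dict())
    pct = {(row["label"], row["protocol"]):
           round(100.0 * row["n_patients"] / COHORT_TOTAL_TARGETS, 1)
           for _, row in df.iterrows()}
    dlpfc_targets = int(
        df.loc[df["outside_dlpfc"] == 0, "n_patients"].sum())
    inconsistent = inconsistent_rows(df)
    return {
        "n_rows": len(df),
        "total": total,
        "per_protocol": per_protocol,
        "per_label": per_label,
        "percentages": pct,
        "dlpfc_targets": dlpfc_targets,
        "inconsistent_labels": sorted(set(
            zip(inconsistent["label"], inconsistent["protocol"]))),
    }


def cohort_target_report(df: pd.DataFrame = None) -> str:
    """Human-readable rendition of the summary."""
    s = cohort_target_summary(df)
    lines = [
        "Cohort target table summary",
        "=" * 40,
        f"Rows                  {s['n_rows']}",
        f"Total targets         {s['total']}",
        f"cTBS / iTBS           {s['per_protocol']['cTBS']} / "
        f"{s['per_protocol']['iTBS']}",
        f"Within dlPFC          {s['dlpfc_targets']}",
        "",
        "label        protocol  n   %",
    ]
    df = load_cohort_targets() if df is None else df
    for _, row in df.iterrows():
        key = (row["label"], row["protocol"])
        lines.append(f"{row['label']:<12} {row['protocol']:<8} "
                     f"{row['n_patients']:>2}  {s['percentages'][key]:>4}")
    if s["inconsistent_labels"]:
        labels = ", ".join(f"{l} ({p})" for l, p in s["inconsistent_labels"])
        lines.append("")
        lines.append(f"NOTE: printed label/full-name hemisphere "
                     f"mismatch in row(s): {labels}")
    return "\n".join(lines)
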