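"""Linkage-rate table: published England cohort counts and derived percentages.

Uses the packaged per-cohort counts of ONS live births, HES-recorded births
and children meeting the main eligibility rule, and derives the three
percentages per cohort (HES births / live births, included / live births,
included / HES births), rounded half-up to one decimal.
"""

from study import write_result

from chcincidence.report import england_linkage_counts, linkage_rates


def main() -> None:
    tab = linkage_rates(england_linkage_counts())
    path = write_result(tab, "linkage_table.csv")
    print(tab.to_string(index=False))
    first, last = tab.iloc[0], tab.iloc[-1]
    print(
        f"\ninclusion rose from {first['pct_included_of_live']}% of live births "
        f"({first['cohort']}) to {last['pct_included_of_live']}% ({last['cohort']}); "
        f"{last['pct_included_of_hes']}% of HES-recorded births link by {last['cohort']}"
    )
    print(f"table -> {path}")


if __name__ == "__main__":
    main()
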