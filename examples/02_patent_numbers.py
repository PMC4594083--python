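"""Normalize patent identifiers and check coverage windows.

Patent numbers arrive in many spellings; matching across databases uses a
comparison key of office code + bare serial (kind code stripped), while
the hyphenated SCPN form is the canonical rendering.
"""

from patentchem import (
    COVERAGE_PRESETS,
    comparison_key,
    in_coverage,
    parse_patent_number,
    to_scpn,
)

for raw in ["WO2008/129280A1", "US4231938", "EP-1481667-B1", "WIPO2006083612"]:
    p = parse_patent_number(raw)
    scpn = to_scpn(p) if p.kind_code else "(no kind code)"
    print(f"{raw:>18} -> key {comparison_key(p):<13} SCPN {scpn:<18} year {p.year}")

# coverage windows: a 2011 WO patent is visible to a source covering
# 1976-present but not to one whose dump ends in 2010
late = parse_patent_number("WO2011123456A1")
print(f"\nWO 2011 patent in SureChEMBL window: {in_coverage(late, COVERAGE_PRESETS['surechembl'])}")
print(f"WO 2011 patent in IBM SIIP window:   {in_coverage(late, COVERAGE_PRESETS['ibm'])}")
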