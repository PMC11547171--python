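"""Standardize a few raw records and partition a cohort by CAS order.

CAS Registry Numbers are assigned roughly chronologically, so sorting by the
first two CAS segments and cutting fixed-size groups yields a time series of
compound batches.
"""

from chronochem import CompoundRecord, Cohort, parse_cas, sort_and_group, standardize
from chronochem.chem_io import cas_check_digit

raw = [
    CompoundRecord("O=C([O-])c1ccccc1.[Na+]", "532-32-1", Cohort.NP, "salt"),
    CompoundRecord("CC(=O)O", "64-19-7", Cohort.NP, "tiny"),
    CompoundRecord("OCC1OC(O)C(O)C(O)C1O", "50-99-7", Cohort.NP, "glucose"),
]
for rec in raw:
    out = standardize(rec)
    print(f"{rec.record_id:8s} kept={out.kept} reason={out.reason.value:8s} -> {out.structure}")
# the benzoate salt keeps only its largest (organic) fragment; acetic acid
# (60 Da) falls below the 70 Da floor; glucose passes untouched

key = parse_cas("7732-18-5")
print(f"\nCAS 7732-18-5 parses to {key.sort_key}, checksum valid: {key.checksum_valid}")

records = []
for i in range(23):
    major, minor = 200 + i, 0
    records.append(
        CompoundRecord(
            "C1CCCCC1", f"{major}-00-{cas_check_digit(major, 0)}", Cohort.NP, f"r{i}"
        )
    )
grouped = sort_and_group(records, group_size=10)
print(f"{len(records)} records at group size 10 -> {len(grouped.groups)} groups, "
      f"{len(grouped.dropped)} tail records dropped")
# only complete groups enter the analysis; the chronological tail is discarded
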