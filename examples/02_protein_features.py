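"""Identify family members and compute protein features.

Scans two proteins with the bundled NAC-domain profile: one carries the
conserved domain (a family member), one is random background.  Also
prints molecular weight, isoelectric point and transmembrane segments.
"""

from homeobias import ProteinRecord, classify_family, compute_features, default_profile

profile = default_profile()
member = ProteinRecord(
    id="candidate1",
    sequence="MSTAGKQLNP" + profile.consensus + "QETNARKLSWDYFHMV" + "L" * 25,
)
background = ProteinRecord(id="candidate2", sequence="MKVTEWQRYPLANDSGHF" * 10)

members = classify_family([member, background], profile)
print("family members:", sorted(members))
for p in (member, background):
    f = compute_features(p, profile)
    print(f"{f.id}: {f.length} aa, MW {f.molecular_weight:.2f} Da, "
          f"pI {f.isoelectric_point:.2f}, domain hits {f.n_domain_hits}, "
          f"membrane_bound={f.membrane_bound} {f.tm_segments}")
# candidate1 carries the domain (one hit) and a C-terminal hydrophobic
# stretch, so it is called a membrane-bound family member; candidate2
# has no hit and stays outside the family.
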