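"""Assign a protein biomarker to an observed mass, then locate a fragment.

An observed linear-mode MALDI mass (singly charged, so m/z ~ mass in Da)
is searched against a peptide database by average molecular mass within a
1% window; a truncation scan then finds which terminal fragment of a
longer protein explains an observed signal.
"""

import importlib.resources

import archaeotype as at

db_path = importlib.resources.files("archaeotype") / "data" / "biomarker_peptides.fasta"
db = at.read_fasta(str(db_path))
print(f"database: {len(db)} published archaeal biomarker peptides")

observed = 6148.08  # base peak observed for a Haloarcula strain
hits = at.tagident_search(observed, db, window_percent=1.0)
print(f"\nproteins within 1% of {observed} Da ({len(hits)} hits):")
print("accession   predicted(Da)  error(%)")
for h in hits[:6]:
    print(f"{h.protein.id:10s}  {h.predicted_mass:12.2f}  {h.error_percent:7.2f}")
print(
    "\nevery hit is within the 1% window; the smallest error is the "
    "tentative assignment\n(taxonomic context decides among near-ties)."
)

# fragment localization: which C-terminal fragment of a 93-residue
# ribosomal protein matches a ~6.1 kDa signal?
protein = next(r for r in db if r.id == "Q8PYQ4")
full_mass = at.average_mass(protein.sequence)
target = at.average_mass(protein.sequence[32:])  # pretend signal
frags = at.truncation_scan(protein, target, tol_percent=0.05, mode="cterm")
print(f"\n{protein.id}: full length {len(protein)} aa, {full_mass:.2f} Da")
for f in frags:
    print(f"  fragment {f.fragment[0]}-{f.fragment[1]} aa -> "
          f"{f.predicted_mass:.2f} Da (error {f.error_percent:.3f}%)")
print("the scan enumerates terminal truncations and reports those whose "
      "average mass\nmatches the observed signal within tolerance.")
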