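"""Myoglobin-fold validation of candidate globin sequences.

Checks three candidates against the sperm whale myoglobin reference: the
reference itself (a textbook globin), a mutant whose proximal F8 histidine
is replaced by alanine (loses heme ligation, must fail), and a domain
truncated before helix G (a defective globin fragment, must fail).
"""

from globinsp import SequenceRecord, StructAlignment, check_mb_fold
from globinsp.globin_fold import default_reference

reference, annotation = default_reference()


def check(name, candidate_seq):
    aln = StructAlignment.from_gapped(
        [reference, SequenceRecord("cand", candidate_seq)]
    )
    result = check_mb_fold(aln, annotation=annotation)
    print(f"{name:22s} F8-His={str(result.f8_his):5s} "
          f"helices={''.join(sorted(result.helices_present)):8s} "
          f"hydrophobic={result.hydrophobic_fraction:.2f} "
          f"-> {'PASS' if result.verdict else 'FAIL'}")


check("reference (self)", reference.sequence)

mutated = list(reference.sequence)
mutated[annotation.ordinal_of("F8")] = "A"
check("F8 His -> Ala", "".join(mutated))

g_start = annotation.ordinal_of("G1")
check("truncated before G", reference.sequence[:g_start]
      + "-" * (len(reference.sequence) - g_start))

# intron positions in helix-relative notation (conserved metazoan introns)
from globinsp import map_intron_position

aln = StructAlignment.from_gapped(
    [reference, SequenceRecord("cand", reference.sequence)]
)
b12 = annotation.ordinal_of("B12")
g7 = annotation.ordinal_of("G7")
print("intron after nt 2 of the B12 codon:",
      map_intron_position(3 * b12 + 2, aln, annotation))
print("intron between the G6 and G7 codons:",
      map_intron_position(3 * g7, aln, annotation))
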