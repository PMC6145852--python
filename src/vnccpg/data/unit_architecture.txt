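# Class-level wiring of the repeating ventral-nerve-cord motorneuron unit.
# One connection per line: PRE POST KIND, KIND in {chemical, electrical}.
# Electrical connections are nonrectifying (unordered pairs); a line with
# PRE == POST is an intersegmental gap junction that links the anterior and
# posterior cells of that class within the unit.
#
# The nine chemical connections named in the study narrative:
AS DA chemical
AS VD chemical
DA DB chemical
DA VD chemical
DB AS chemical
DB VD chemical
VD VA chemical
VD VB chemical
VA VD chemical
# Tenth chemical connection, FIGURE-DERIVED: read from the circuit diagram,
# not from the text (the text enumerates only nine). Editable; swapping it
# for another figure-derived candidate only relabels one genotype entry.
VB VA chemical
# Electrical connections:
DA VA electrical
VD VA electrical
VD VD electrical
VB VB electrical
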