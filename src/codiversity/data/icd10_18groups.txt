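# Default 18-group cause-of-death scheme, built on ICD-10 chapters.
# Format: one entry per line, "label: range[, range...]" with inclusive
# three-character code ranges. Blank lines and '#' comments ignored.
#
# Communicable block (4 groups)
infectious: A00-B99
maternal: O00-O99
perinatal: P00-P96
congenital: Q00-Q99
# Noncommunicable block (12 groups)
neoplasms: C00-D48
blood: D50-D89
endocrine: E00-E90
mental: F00-F99
neurological: G00-G99
eye_ear: H00-H59, H60-H95
cardiovascular: I00-I99
respiratory: J00-J99
digestive: K00-K93
skin: L00-L99
musculoskeletal: M00-M99
genitourinary: N00-N99
# External and ill-defined
external: S00-T98, V01-Y98
ill_defined: R00-R99
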