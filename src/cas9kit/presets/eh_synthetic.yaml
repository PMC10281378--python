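# EH CRISPR-Cas9 system preset.
#
# Architecture dimensions follow the published EH system characterization:
# 36-bp repeats separated by a 29-bp spacer, an ~100-nt tracrRNA whose first
# 73 nt (beginning with an 18-nt anti-repeat) are retained in the sgRNA
# backbone, a GAAA tetraloop linker, 23-nt guide spacers, a TGGN editing PAM,
# a blunt cut 3 nt from the PAM, and TNNN (in vivo) / NNNNNNN (in vitro)
# randomized PAM libraries.
#
# SYNTHETIC SEQUENCES: the repeat, array spacer, and tracrRNA sequences below
# are synthetic stand-ins generated with the published geometry (the real
# sequences appear only in figure panels and are not machine-readable); the
# tracrRNA's first 18 nt are the reverse complement of the repeat's 3' 18 nt
# carrying 4 substitutions (the anti-repeat).  The in vivo protospacer anchor
# IS the published target sequence.
name: eh
repeat: ATTGTTTAGCCTTATACCTTTGTAGTTCTGCTTTAA          # 36 nt, synthetic
array_spacer: TCCTATCGTCACATAAGGACCGCCTTACA           # 29 nt, synthetic
tracrrna: CTACAGTAGAACTACACAATTCCCTCCCGAAAGGGAGGGATTCGCCGTGCTGAAAAGCACGGCCCCAAATTCAGGAATGCTAAGCATGGTGGCAGCGTAG  # 100 nt, synthetic
anchor: CCTGTATATCGTGCGAAAAAGGATGGATA                 # published in vivo protospacer
invivo_pattern: TNNN
invitro_pattern: NNNNNNN
editing_pam: TGGN
guide_length: 23
sgrna:
  keep_repeat: 18        # 3' repeat nucleotides retained in the crRNA part
  repeat_from: 3prime
  linker: GAAA
  keep_tracr: 73
cut:
  offset: 3              # nt from the PAM-proximal protospacer end
  overhang: 0            # blunt
orf_len_aa: 1070
anti_repeat_mismatches: 4
recomb_arms:
  upstream: 145
  downstream: 163
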