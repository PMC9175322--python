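# Default avoidability scheme shipped with lifegap.
# Synthetic working default covering the major avoidable-cause families;
# NOT the official OECD/Eurostat avoidable-mortality list. Replace with a
# user-supplied file for production analyses. Rules are evaluated in order;
# first match wins; unmatched codes fall through to non_avoidable.
range_start,range_end,category
A00,A09,treatable
A15,A19,treatable_and_preventable
A20,B99,treatable
C33,C34,preventable
E10,E14,treatable_and_preventable
F10,F16,preventable
I10,I15,treatable_and_preventable
I20,I25,ihd
J09,J11,preventable
J12,J18,treatable
J40,J44,preventable
J45,J46,treatable
O00,O99,treatable
P00,P96,treatable
Q00,Q99,treatable
V01,Y89,preventable
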