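>murine_eIF4E|Mus_musculus|reference 1L8B numbering; anchors W43 W46 W56 W73 W102 E103 R112 W130 R157 K162 W166
MATVEPETTPTPNPPTTEEEKTESNQEVANPEHYIKHPLQNRWALWFFKNDKSKTWQANL
RLISKFDTVEDFWALYNHIQLSSNLMPGCDYSLFKDGIEPMWEDEKNKRGGRWLITLNKQ
QRRSDLDRFWLETLLCLIGESFDDYSDDVCGAVVNVRAKGDKIAIWTTECENREAVTHIG
RVYKERLGLPPKIVIGYQSHADTATKSGSTTKNRFVV
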