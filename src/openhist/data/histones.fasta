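>sp|P68431|H31_HUMAN Histone H3.1 OS=Homo sapiens GN=H3C1
MARTKQTARKSTGGKAPRKQLATKAARKSAPATGGVKKPHRYRPGTVALREIRRYQKSTE
LLIRKLPFQRLVREIAQDFKTDLRFQSSAVMALQEACEAYLVGLFEDTNLCAIHAKRVTI
MPKDIQLARRIRGERA
>sp|Q71DI3|H32_HUMAN Histone H3.2 OS=Homo sapiens GN=H3C15
MARTKQTARKSTGGKAPRKQLATKAARKSAPATGGVKKPHRYRPGTVALREIRRYQKSTE
LLIRKLPFQRLVREIAQDFKTDLRFQSSAVMALQEASEAYLVGLFEDTNLCAIHAKRVTI
MPKDIQLARRIRGERA
>sp|P84243|H33_HUMAN Histone H3.3 OS=Homo sapiens GN=H3-3A
MARTKQTARKSTGGKAPRKQLATKAARKSAPSTGGVKKPHRYRPGTVALREIRRYQKSTE
LLIRKLPFQRLVREIAQDFKTDLRFQSAAIGALQEASEAYLVGLFEDTNLCAIHAKRVTI
MPKDIQLARRIRGERA
>sp|P62805|H4_HUMAN Histone H4 OS=Homo sapiens GN=H4C1
MSGRGKGGKGLGKGGAKRHRKVLRDNIQGITKPAIRRLARRGGVKRISGLIYEETRGVLK
VFLENVIRDAVTYTEHAKRKTVTAMDVVYALKRQGRTLYGFGG
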