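>ank_consensus synthetic canonical 33-aa ankyrin unit
DKDGRTPLHLAASNGHLEVVKLLLEAGADVNAK
>ank_seed_01 synthetic ankyrin seed unit
DNDNRTPLHLVACGGHLELVELLLDAGADINAQ
>ank_seed_02 synthetic ankyrin seed unit
SKEGETPIHLVAYNRHLDVVRLLIERGVDVNAK
>ank_seed_03 synthetic ankyrin seed unit
DKNGRTPIHLAAYEGHKEVVRLLLDAGVDVNAT
>ank_seed_04 synthetic ankyrin seed unit
NKEGETPLHLVASGGHKELAKLILDHGADVNAK
>ank_seed_05 synthetic ankyrin seed unit
DKEGKTPIHFAARKRHLEIVRVIIEAGADVNSK
>ank_seed_06 synthetic ankyrin seed unit
SNDGRTPLHLAASKRNLELVKLLIDAGADVNSK
>ank_seed_07 synthetic ankyrin seed unit
DKDGRTPLHIAACNGNPEVVRLLLKAGVDVNAQ
>ank_seed_08 synthetic ankyrin seed unit
DRDGKTPLHIAAARGHLELARVIIKAGADPNAK
>ank_seed_09 synthetic ankyrin seed unit
DKDNRTPLHFAACEGHLDLVKLLLEAGVDVNAQ
>ank_seed_10 synthetic ankyrin seed unit
NNDNETPLHLAASRRHPEVAKLILEHGADVNAK
>ank_seed_11 synthetic ankyrin seed unit
DKDNKTPIHLAACNRHLEIVRLILERGVDVNAK
>ank_seed_12 synthetic ankyrin seed unit
DKDNQTPIHLAATNRHLEVAKVLLDYGADVNAK
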