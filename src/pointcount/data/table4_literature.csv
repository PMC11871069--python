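species,avg_min_n,range_lo,range_hi,references
Multispecies survey (general),241,20,828,Augenfeld et al.; Blake; Bub et al.; Buskirk and McDonald; DeSante; Hanowski and Niemi; Howe et al.; Heckscher; Heltzel and LeBerg; Hutto et al.; Latta et al.; LeGrand; Pierce and King; Preston et al.; Rolek et al.; Rotenberry and Knick; Smith et al.; Swanson et al.; Thompson and Schwalbach; Thompson et al.; Twedt and Somershoe
Acadian Flycatcher,94,23,287,Smith et al.; Thompson et al.
American Crow,264,181,347,Thompson et al.
American Redstart,124,9,200,Smith et al.
Blue-gray Gnatcatcher,108,44,200,Smith et al.
Brown-headed Cowbird,178,44,467,Smith et al.; Thompson et al.
Carolina Chickadee,200,,,Smith et al.
Carolina Wren,176,33,994,Smith et al.
Downy Woodpecker,920,632,1208,Thompson et al.
Eastern Wood-Pewee,306,210,401,Thompson et al.
Great Crested Flycatcher,849,583,1114,Thompson et al.
Hooded Warbler,314,9,1655,Smith et al.; Thompson and Schwalbach
Indigo Bunting,205,9,764,Smith et al.; Thompson and Schwalbach
Kentucky Warbler,286,9,1561,Smith et al.; Thompson and Schwalbach
Northern Cardinal,99,20,200,Smith et al.
Northern Parula,130,23,200,Smith et al.
Ovenbird,226,155,297,Thompson et al.
Pileated Woodpecker,279,189,368,Thompson et al.
Prothonotary Warbler,93,23,200,Smith et al.
Red-bellied Woodpecker,115,33,498,Smith et al.; Thompson and Schwalbach
Red-eyed Vireo,130,23,398,Smith et al.; Thompson et al.
Rufous-sided Towhee,365,9,2066,Smith et al.; Thompson and Schwalbach
Scarlet Tanager,207,142,272,Thompson and Schwalbach
Summer Tanager,113,9,200,Smith et al.
Swainson's Warbler,61,,,Peters et al.
Tufted Titmouse,84,37,200,Smith et al.; Thompson and Schwalbach
White-breasted Nuthatch,636,437,835,Thompson and Schwalbach
Wood Thrush,135,15,414,Smith et al.; Thompson and Schwalbach
Worm-eating Warbler,417,286,547,Thompson and Schwalbach
Yellow-billed Cuckoo,126,37,419,Smith et al.; Thompson and Schwalbach
Yellow-throated Vireo,124,9,200,Smith et al.
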