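#categories: Sex,Position,Venation,Habit
term,category,canonical
bark,Structure,
trunk,Structure,
crown,Structure,
branch,Structure,
branchlet,Structure,
twig,Structure,
shoot,Structure,
stem,Structure,
bud,Structure,
leaf,Structure,
leaflet,Structure,
petiole,Structure,
blade,Structure,
lamina,Structure,
margin,Structure,
apex,Structure,
base,Structure,
midrib,Structure,
vein,Structure,
sheath,Structure,
stipule,Structure,
cone,Structure,
cone scale,Structure,
bract,Structure,
scale,Structure,
scale,Shape,
seed,Structure,
seed wing,Structure,
wing,Structure,
ovule,Structure,
pollen,Structure,
microsporophyll,Structure,
sporophyll,Structure,
strobilus,Structure,
peduncle,Structure,
pedicel,Structure,
flower,Structure,
fruit,Structure,
root,Structure,
resin,Structure,
cuticle,Structure,
stomata,Structure,
phyllode,Structure,
rachis,Structure,
internode,Structure,
node,Structure,
columella,Structure,
ligule,Structure,
red,Coloration,
green,Coloration,
dark green,Coloration,
pale green,Coloration,
yellowish,Coloration,
yellow,Coloration,
orange,Coloration,
brown,Coloration,
reddish-brown,Coloration,
dark brown,Coloration,
gray,Coloration,
ash-gray,Coloration,gray
grey,Coloration,gray
glaucous,Coloration,
black,Coloration,
blackish,Coloration,
white,Coloration,
whitish,Coloration,
purple,Coloration,
purplish,Coloration,
chestnut,Coloration,
coppery,Coloration,
silvery,Coloration,
ovate,Shape,
obovate,Shape,
lanceolate,Shape,
oblanceolate,Shape,
elliptic,Shape,
elliptical,Shape,elliptic
oblong,Shape,
linear,Shape,
acicular,Shape,
subulate,Shape,
falcate,Shape,
deltoid,Shape,
triangular,Shape,
rhombic,Shape,
orbicular,Shape,
rounded,Shape,
globose,Shape,
spherical,Shape,globose
subglobose,Shape,
ovoid,Shape,
obovoid,Shape,
ellipsoid,Shape,
conical,Shape,
conic,Shape,conical
cylindrical,Shape,
cylindric,Shape,cylindrical
columnar,Shape,
fusiform,Shape,
pyramidal,Shape,
dome-shaped,Shape,
flattened,Shape,
compressed,Shape,
keeled,Shape,
acute,Shape,
acuminate,Shape,
obtuse,Shape,
mucronate,Shape,
apiculate,Shape,
cuneate,Shape,
cordate,Shape,
truncate,Shape,
attenuate,Shape,
u-like,Shape,
scale-like,Shape,
awl-shaped,Shape,
needle-like,Shape,
smooth,Texture,
rough,Texture,
leathery,Texture,
coriaceous,Texture,leathery
woody,Texture,
papery,Texture,
resinous,Texture,
fibrous,Texture,
corky,Texture,
scaly,Texture,
wrinkled,Texture,
furrowed,Texture,
rugose,Texture,
striate,Texture,
glossy,Texture,
shiny,Texture,glossy
lustrous,Texture,glossy
dull,Texture,
waxy,Texture,
exfoliating,Texture,
peeling,Texture,exfoliating
flaking,Texture,
rigid,Texture,
stiff,Texture,rigid
flexible,Texture,
thick,Texture,
thin,Texture,
glabrous,Pubescence,
pubescent,Pubescence,
hairy,Pubescence,pubescent
tomentose,Pubescence,
villous,Pubescence,
puberulent,Pubescence,
glabrescent,Pubescence,
ciliate,Pubescence,
erect,Orientation,
spreading,Orientation,
patent,Orientation,spreading
pendulous,Orientation,
drooping,Orientation,pendulous
nodding,Orientation,
ascending,Orientation,
descending,Orientation,
appressed,Orientation,
adpressed,Orientation,appressed
incurved,Orientation,
recurved,Orientation,
reflexed,Orientation,
horizontal,Orientation,
oblique,Orientation,
twisted,Orientation,
imbricate,Architecture,
whorled,Architecture,
opposite,Architecture,
subopposite,Architecture,
alternate,Architecture,
decussate,Architecture,
spiral,Architecture,
spirally arranged,Architecture,spiral
crowded,Architecture,
dense,Architecture,
lax,Architecture,
clustered,Architecture,
solitary,Architecture,
paired,Architecture,
terminal,Position,
axillary,Position,
lateral,Position,
basal,Position,
apical,Position,
subterminal,Position,
sessile,Position,
deciduous,Duration,
persistent,Duration,
evergreen,Duration,
caducous,Duration,
annual,Duration,
perennial,Duration,
adult,Duration,
juvenile,Duration,
young,Duration,juvenile
mature,Duration,adult
male,Sex,
female,Sex,
bisexual,Sex,
unisexual,Sex,
monoecious,Sex,
dioecious,Sex,
tree,LifeForm,
shrub,LifeForm,
liana,LifeForm,
herb,LifeForm,
emergent,Habit,
spreading-crowned,Habit,
buttressed,Habit,
large,Size,
small,Size,
minute,Size,
broad,Size,
narrow,Size,
elongate,Size,
short,Size,
long,Size,
numerous,Count,
few,Count,
many,Count,
single,Count,
parallel,Venation,
net-veined,Venation,
many-veined,Venation,
free,Architecture,
fused,Architecture,
united,Architecture,fused
entire,Shape,
serrate,Shape,
denticulate,Shape,
crenate,Shape,
revolute,Shape,
undulate,Shape,
present,Character,
absent,Character,
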